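# patmut

Extended-sequence-context models of germline mutation rates via **k-mer
pattern partitions**, with a gene-level engine that turns a trained rate
model into per-transcript expected counts of functional mutation classes,
Poisson-binomial burden p-values, and loss-of-function constraint scores
(O/E, LOEUF).

It is aimed at statistical geneticists who want to (a) estimate how the
DNA sequence surrounding a position modulates its point-mutation and
indel rates without overfitting at large k, and (b) use those rates to
ask whether individual genes carry more (disease) or fewer (constraint)
functional mutations than expected.

## The model

The mutation rate of a site depends on its sequence context, but a free
rate per k-mer becomes hopelessly sparse beyond 5-mers.  patmut instead
partitions all k-mers with a set of IUPAC ambiguity patterns
P = {p₁, …, pₙ} such that **every k-mer is matched by exactly one
pattern**, and pools counts within each pattern.  With Mᵢ mutated and Uᵢ
unmutated sites matching pattern pᵢ, the partition minimizes the
penalized binomial deviance

    loss(P) = Σᵢ [ −2 (Mᵢ log rᵢ + Uᵢ log(1 − rᵢ)) + c ]

where the pattern rate is regularized toward the global mean rate μ by a
pseudo count α:

    rᵢ = (Mᵢ + α) / (Mᵢ + Uᵢ + α / μ)

At c = 2 the loss is exactly the AIC of the binomial likelihood model.
The optimum over all partitions reachable by recursively splitting one
position's IUPAC code into two disjoint covering sub-codes (a
*two-partition*) satisfies

    f(p) = min( loss({p}),
                min over positions i, (x, y) ∈ TwoPartition(p[i]) of
                    f(p[:i] + x + p[i+1:]) + f(p[:i] + y + p[i+1:]) )

and is computed bottom-up by dynamic programming (exponential in k; a
greedy variant that commits to the single most promising split handles
larger k).  α and c are chosen by repeated 2-fold cross-validation with
hypergeometric table splits; fits are scored out of sample with
Nagelkerke's pseudo r².

SNV contexts are strand-collapsed into the six classes A→C, A→G, A→T,
C→A, C→G, C→T.  Indels are represented by breakpoint context k-mers:
since an indel's exact placement is usually ambiguous, all equivalent
placements are enumerated and one is chosen at random per event;
insertions count the breakpoint k-mer and its reverse complement,
deletions count start- and end-breakpoint k-mers with their reverse
complements.

The gene-level engine enumerates every possible point mutation of a
transcript, classifies it (synonymous, missense, nonsense, start/stop
disruption, essential-splice, inframe/frameshift indel), attaches the
pattern rate of its context, rescales rates so the genome-wide means are
1.28 × 10⁻⁸ per base per generation (SNVs) and 0.68 × 10⁻⁹ (indels), and
converts each per-generation rate r into the probability of observation
across n_gen transmitted generations, r_scaled = 1 − (1 − r)^(2·n_gen).
Per-gene counts are then Poisson-binomial; burden p-values and the 90%
interval of the expected count come from Monte-Carlo sampling, and LoF
constraint is summarized as (obs + 0.5)/(exp + 0.5) and LOEUF =
(obs + 0.5)/(lower90 + 0.5).

## Worked example

Everything below is synthetic and seeded; no external data is needed.

```python
from patmut.simulate import example_truth, simulate_genome, simulate_mutations
from patmut.kmer_counting import count_snv_kmers
from patmut.model_selection import fit_with_cv, CVConfig

genome, mask = simulate_genome(500_000, seed=1)
truth = example_truth()            # known 4-pattern C>T partition (CpG hot)
muts = simulate_mutations(genome, mask, truth, seed=2)

table = count_snv_kmers(muts, genome, mask, k=3)["C>T"]
model, cv = fit_with_cv(table, CVConfig(seed=3))
print(cv.selected)
for p in model.patterns:
    print(p.pattern, p.M, p.U, round(p.r, 5))
```

prints

```
(2.0, 10.0)
ACH    93.0  47725.0  0.00197
TCH    28.0  47922.0  0.00062
SCH   416.0  66351.0  0.00623
NCG   867.0  41313.0  0.02046
```

The cross-validated fit recovers the generating partition exactly —
`NCG` is the hot CpG pattern (fitted rate 0.020 against a truth of
0.020), `SCH`/`ACH`/`TCH` are the strong/weak-flank C patterns — and on
an independently simulated test genome the model reaches a Nagelkerke
r² of 0.089, reflecting the intrinsic randomness of where mutations
actually land.

The same workflow is available from the shell:

```bash
patmut simulate --length 500000 --seed 1 --out-dir fixtures/
patmut count-snv --genome fixtures/genome.fa --mask fixtures/mask.bed \
    --mutations fixtures/mutations.tsv --k 3 --out-prefix counts/snv
patmut train --counts counts/snv.C_T.tsv --seed 3 --out models/C_T.tsv
patmut evaluate --model models/C_T.tsv --counts test_counts.tsv
patmut genes --annotation genes.gtf --genome fixtures/genome.fa \
    --snv-models models/ --indel-models indel_models/ \
    --mutations observed.tsv --ngen 5e6 --out genes.tsv
```

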