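# primercover

Multiplexed primer/probe design by a linearly scaling approximation of
minimum set coverage.

## The problem

Multiplex assays — multiplex PCR, digital multiplex ligation assays
(dMLA) — detect many genomic targets in one reaction and need a panel
of short oligonucleotides (primers or probes, ~20 nt) that together
hybridise to as much of a heterogeneous target set as possible.
Choosing the smallest panel that covers a set of target sequences is
the minimum set-cover problem, which is NP-hard, so exact optimisation
does not scale to the large, diverse sequence collections met in
clinical microbiology, virus surveillance or antimicrobial-resistance
screening. `primercover` computes a near-optimal cover in time linear
in the number of input bases.

## The method

Given n target sequences and a primer length k:

1. **Enumerate.** Every k-length window of every sequence is a primer
   candidate (windows containing an ambiguous base are skipped).  Each
   distinct k-mer p is indexed by its *coverage*
   C(p) = { i : p is a substring of sequence i }.
2. **Filter (optional).** Candidates with GC fraction outside
   [gc_min, gc_max], or with |GC(first half) − GC(second half)| above a
   bound, are removed (the half rule targets adjacent-probe designs).
3. **Cluster.** Candidates with identical coverage sets are
   interchangeable and are merged into *primer clusters*; the shared
   coverage set is the cluster's *sequence group*.
4. **Cut off.** Clusters with fewer than `min_primer_group_size`
   primers or fewer than `min_sequence_group_size` sequences are
   dropped.
5. **Rank and cumulate.** Clusters are sorted by sequence-group size
   (then primer-group size), and along that order the running fraction
   of sequences covered — the *cumulative coverage* — is computed and
   rounded to d decimals.
6. **Collapse.** Consecutive clusters tied on rounded cumulative
   coverage add little or no new coverage; only the largest of each tie
   group is kept.

The result is a ranked cluster table, the id/header/sequence
conversion table, the excluded-sequence table, a boolean
cluster-by-sequence *primer matrix* and its heatmap.  Internally,
windows are packed two bits per base into 64-bit integers and grouped
with a single sort, which is what keeps the cost linear in practice on
multi-megabase inputs.

## Worked example

Generate a small synthetic target set — 12 sequences of 120 bp, being
mutated copies (3 % substitutions) of 3 ancestral sequences — and
design a panel:

```sh
primercover synth -n 12 -b 120 --mode family --n-ancestors 3 \
    --substitution-rate 0.03 --seed 5 -o targets.fasta
primercover run targets.fasta --out design --min-sequence-group-size 2
```

`design/description.txt` then reads:

```
Multiplexed primer design summary
input sequences: 12
input bases: 1440
primer clusters: 4
covered sequences: 12
excluded sequences: 0
final cumulative coverage: 1.0
...
```

and `design/primer_candidates.tsv` (primer column truncated here):

```
cluster_id  seq_ids   primer_group_size  sequence_group_size  cumulative_coverage
1           3,6,9,12  16                 4                    0.3333
2           1,4,7,10  9                  4                    0.6667
3           5,8,11    18                 3                    0.9167
4           2,8,11    18                 3                    1.0
```

Reading: cluster 1 offers 16 interchangeable 20-mers, any one of which
hybridises to exactly sequences {3, 6, 9, 12} — a third of the input
(cumulative coverage 0.3333).  Adding one primer from each subsequent
cluster raises the covered fraction to 0.6667, 0.9167 and finally 1.0:
four oligonucleotides cover all twelve targets.  `design/heatmap.png`
shows the same matrix graphically, dark cells marking coverage.

The same pipeline is available in Python:

```python
from primercover import Config, run_pipeline
result = run_pipeline("targets.fasta", Config(min_sequence_group_size=2))
result.primer_candidates   # the table above, as a DataFrame
```

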