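# premascan

Predicting single-allele repair outcomes of programmable-nuclease cuts
through microhomology-mediated end joining (MMEJ).

When a CRISPR-Cas9 or TALEN double-strand break (DSB) is repaired by the
versatile non-homologous end joining pathway, the result is a diverse
mix of indels — a problem for anyone who needs one defined allele, from
F0 knockout screens in zebrafish to gene-correction work in cultured
human cells. MMEJ offers a way out: it anneals a pair of identical
direct repeats ("microhomology arms", ≥ 3 bp) flanking the break and
deletes the intervening sequence plus one repeat copy, yielding a
single stereotyped deletion allele. `premascan` finds the cut sites
where that stereotyped outcome is predicted to dominate.

## The model

Every direct-repeat pair spanning a break defines one candidate
deletion. Each is scored with the Bae-style Pattern Score

```
score = 100 · round(e^(−Δ/20), 3) · (AT + 2·GC)
```

where Δ is the deletion length (distance between the two arm copies)
and AT/GC count the bases of one arm. The per-locus sum is the
Microhomology Score, and the score-weighted share of frame-shifting
deletions (Δ mod 3 ≠ 0) is the out-of-frame score.

Local repeat pairs compete for the repair machinery. Two criteria
capture whether one pattern wins outright:

1. **Proximity** — the top-ranked pattern's arms are separated by ≤ 5 bp
   of intervening sequence;
2. **Low competition** — the top Pattern Score is ≥ 1.5× the second.

The four combinations partition candidate sites into Groups 1–4.
Group 4 sites are predicted to yield a Predominant MMEJ Allele (PreMA):
a modal mutant allele that is the top-predicted deletion, comprises
≥ 50 % of mutant reads, with > 20 % mutagenic efficiency. The package
also implements the observed-outcome side of that definition: allele
tables are classified against the predicted landscape (≤ 2 off-arm
substitutions tolerated) into wildtype / top-MH / other-MMEJ / other
mutant, giving the mutagenic efficiency, Microhomology Fraction, Top MH
Fraction, and the PreMA call.

## Worked example

Scan a sequence for SpCas9 (NGG) sites and keep the PreMA candidates:

```python
from premascan import ScanConfig, TargetingScheme, scan

sites = scan(sequence, TargetingScheme(pam="NGG", cut_offset=-3),
             ScanConfig(window=40, min_arm=3))
for s in sites:
    if s.recommended:
        print(s.site_id, s.guide_seq, s.profile.ratio,
              s.predicted.deletion_len)
```

Or from the shell, on a generated demo locus:

```
$ premascan fixtures --spec spec.yaml --out demo/     # plant a test locus
$ premascan score --fasta demo/planted.fa --cut 60 --window 20
locus_id  left_start  right_start  ...  deletion_len  intervening_len  pattern_score
planted           54           60  ...             6                0          741.0
microhomology_score=741.0
out_of_frame_score=0.0
group=4 ratio=inf slope=n/a
```

One repeat pair, arms abutting the break (intervening 0, criterion 1),
no competitor (ratio ∞, criterion 2): Group 4. The predicted repair
outcome is the single 6 bp deletion collapsing the two arm copies; its
Pattern Score is 100 · round(e^(−6/20), 3) · 12 = 741.0 (6 bp arm, 5
G/C), and with no competing pattern the out-of-frame score is 0 — an
in-frame reagent.

Classify observed alleles against a locus:

```
$ premascan outcomes --alleles alleles.csv --locus locus.fa --cut 60 --window 25
```

prints total/mutant/excluded reads, mutagenic efficiency, the two
fractions, and the PreMA call.

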