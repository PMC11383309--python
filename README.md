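# receptorkit

Analysis toolkit for studies of mitophagy-receptor interactions, covering the
three computational workflows such studies combine:

1. **Pull-down interactor calling** from label-free quantification (LFQ)
   proteomics — a tagged receptor fragment (e.g. NIX-GST or BNIP3-GST) is
   affinity-purified from lysate alongside a tag-only control, and proteins
   enriched over the control are candidate interactors.
2. **Molecular-dynamics interface metrics** — per-frame quantities describing
   how a LIR peptide engages its binding site on a WIPI β-propeller.
3. **Structure-prediction screen ranking** — classification of
   receptor–WIPI prediction screens by interface confidence (ipTM).

Everything is exercised against synthetic data with known ground truth; the
package never runs a search engine, a simulation or structure inference.

## The methods

**Mode normalization.** Protein intensities are log2-transformed after a
quantifiability filter (non-contaminant, ≥ 2 unique peptides). For every pair
of samples *(i, j)* the mode *m<sub>ij</sub>* of the distribution of per-protein
log2 ratios *x<sub>pi</sub> − x<sub>pj</sub>* estimates the systematic offset
between the samples: the bulk of a pull-down is shared background, so the
dominant peak tracks the unchanged majority even when a minority of proteins
is strongly differential. Per-sample factors *f* minimize
Σ<sub>i&lt;j</sub> (f<sub>i</sub> − f<sub>j</sub> − m<sub>ij</sub>)² subject to
Σ f = 0, which for an antisymmetric mode matrix is the row-mean closed form
f<sub>i</sub> = (1/n) Σ<sub>j</sub> m<sub>ij</sub>; values are normalized as
x′ = x − f.

**MNAR imputation.** Missing LFQ values concentrate at low abundance, so each
missing cell in sample *s* is drawn from a down-shifted Gaussian

> μ<sub>s</sub> = median(observed<sub>s</sub>) − 1.8 · sd(observed<sub>s</sub>),  σ<sub>s</sub> = 0.3 · sd(observed<sub>s</sub>)

computed from that sample's observed log2 intensities (sample sd, n−1).

**Enrichment.** Per protein, log2 fold change = mean(bait) − mean(control)
with a two-sample t-test (pooled-variance Student t by default, Welch as an
option) and Benjamini–Hochberg FDR across all tested proteins; top hits are
ranked by fold change.

**Interface metrics**, per trajectory frame: *n*<sub>h-bonds</sub> — backbone
N–H···O=C hydrogen bonds between two residue ranges (N···O ≤ 3.5 Å and
N–H···O ≥ 150° when amide hydrogens are present); *d*<sub>TRP</sub> — minimum
distance from any heavy atom of the LIR tryptophan to a Cα anchor in the
binding pocket (insertion depth); *d*<sub>pocket</sub> — minimum sidechain
heavy-atom distance between two pocket residues (pocket opening).

**Screen ranking.** ipTM scores in [0, 1] are ranked descending; predictions
with ipTM > 0.5 (strictly) are putative hits, and scores within ±0.05 of the
threshold are annotated as borderline.

## Worked example

Generate the default synthetic pull-down (2000 proteins, GST vs bait, 3
replicates each, true per-sample shifts in ±1.5 log2, 20 spiked interactors
at +2 log2, intensity-dependent missingness) and run the full stack:

```python
import receptorkit as rk

table, design, truth = rk.generate_lfq_dataset(rk.LfqSimConfig(seed=0))
log2 = rk.log2_transform(rk.filter_quantifiable(table))
fit = rk.estimate_factors(rk.pairwise_modes(log2))
print(fit.factors.round(3))
```

```
GST_1     0.264
GST_2    -0.940
GST_3     0.056
bait_1    0.683
bait_2    0.526
bait_3   -0.589
```

The recovered factors match the generator's true shifts (0.269, −0.943,
0.053, 0.697, 0.517, −0.592) to ~0.01 log2 units; `fit.residual_rms`
(0.025) reports how inconsistent the pairwise modes were with any single set
of per-sample offsets. Continuing,

```python
norm = rk.apply_factors(log2, fit)
imputed, mask = rk.impute(norm, seed=0)
enr = rk.compare_groups(imputed, design, "bait", "GST", observed_mask=~mask)
print(enr.sort_values("rank").head(5)[["log2fc", "t_stat", "p_value", "rank"]].round(4))
```

```
            log2fc   t_stat  p_value  rank
protein_id
P00756      2.6288   1.8998   0.1303     1
P00013      2.3569   6.9168   0.0023     2
P01215      2.2957   2.4442   0.0709     3
P00910      2.2417   6.5135   0.0029     4
P01417      2.1435  10.1980   0.0005     5
```

Ranks 2, 4 and 5 are true spiked interactors (large, tight fold changes);
ranks 1 and 3 are detection-boundary artifacts — proteins observed in the
bait samples but imputed low in the control — recognizable by their large
p-values. `rk.top_hits(enr, n=20)` applies the fold-change and q-value
thresholds.

The same `run-all` pipeline is available from the shell:

```sh
receptorkit run-all --config config.yaml --out results/
receptorkit screen classify --in tests/data/screen_scores.tsv
```

The screen command prints the six-receptor example panel ranked BNIP3 (0.66),
NIX (0.65), FKBP8 (0.58), TEX264 (0.54), FAM134C (0.46), CCPG1 (0.2), with
the first four flagged as hits at the 0.5 threshold and FAM134C and TEX264
annotated as borderline.

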