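# ciliascreen

Tools for quantifying lipid-probe staining at primary cilia and for
scoring FACS-sorted pooled CRISPR screens, with synthetic ground-truth
generators that make every stage testable end to end.

The primary cilium is a thin membrane protrusion where hedgehog signal
transduction takes place, and the lipid composition of its membrane —
in particular the pool of accessible cholesterol and its sequestration
by sphingomyelin — modulates signaling. Two experimental readouts
dominate this kind of study, and this package implements the
computational side of both:

1. **Imaging.** Cells expressing a ciliary marker (e.g. ARL13B-GFP) are
   stained with toxin-derived lipid probes (PFO\*, OlyA, ALOD4) and
   imaged as confocal z-stacks. Cilia are segmented in the marker
   channel and the probe's ciliary staining is normalized to the
   surrounding plasma membrane — the **C/P ratio**.
2. **Screening.** A pooled sgRNA library is transduced into reporter
   cells, a tail of the reporter distribution (e.g. the bottom 10%
   under saturating ligand) is FACS-sorted, and guide abundances in the
   sorted versus unsorted populations reveal genes whose loss shifts
   signaling.

## Methods at a glance

**Cilia detection.** Max-z projection of the marker channel → 2D median
filter (square window, radius *r*) → signal/noise threshold → connected
components ("potential cilia") → five tests per component:

- area ∈ [20, 500] px,
- eccentricity ≥ 0.85 (from the normalized second central moments:
  e = √(1 − λ₂/λ₁)),
- solidity ≥ 0.8 (area over rasterized convex-hull area),
- mean intensity ≥ a floor,
- max-Feret length ∈ [10, 120] px,

plus optional exclusion of border-touching objects. Only components
passing **all** tests are "true cilia". The default threshold is a
robust background model (median + 10·1.4826·MAD of the filtered
projection); absolute and quantile thresholds are also supported.

**C/P ratio.** For each cilium the probe channel is measured plane by
plane inside the cilium mask and inside a plasma-membrane ring (the
mask dilated by a disk of radius 5 px, minus the mask). With Cᵢ and Pᵢ
the per-plane means,

    C/P = maxᵢ Cᵢ / maxⱼ Pⱼ   (division mode, default)
    C/P = maxᵢ Cᵢ − maxⱼ Pⱼ   (subtraction mode)

each maximum taken at its own brightest focal plane. Ciliation
frequency is the cilia count over the nuclei count of a field.

**Screen scoring.** With RPM-normalized counts and pseudocount c = 0.5,
each guide gets ratio (RPMsorted + c)/(RPMunsorted + c); a gene's
enrichment is the arithmetic mean of its guides' ratios. Significance
comes from permuting guide ratios across genes (preserving guide
counts): p = (1 + #{|log₂ null| ≥ |log₂ obs|})/(Nperm + 1), with
Benjamini–Hochberg FDR over targeting genes and hits called at
FDR ≤ 0.1. Pathway roll-up drops genes with RPKM 0 in both RNAseq
replicates and splits hits into positive/negative regulators according
to the sorting design.

**Reporting statistics.** Exact two-sided Mann–Whitney U (full null
enumeration for tie-free samples with n₁+n₂ ≤ 20; p = 2·min(tails)
capped at 1), Kruskal–Wallis, a univariate ROUT-style outlier filter
(median fit, 68.27th-percentile robust scale, FDR-controlled removal at
level Q), violin summaries (mean + IQR), median fold changes, ΔCt
(2^−ΔCt), and per-DNA normalization.

## Worked example

```python
import ciliascreen as cs

truth = cs.CiliumTruth(center=(64.0, 64.0), orientation_deg=30.0,
                       probe_intensity_cilium=200.0)
stack, table = cs.make_cilium_stack([truth], shape=(5, 128, 128),
                                    membrane_level=100.0)
cilia = cs.detect_cilia(stack, cs.DetectionParams(median_radius_px=0))
quant = cs.quantify_stack(stack, cilia)[0]
print(len(cilia), quant.cp_value)   # -> 1 2.0
```

One capsule-shaped cilium with probe level 200 a.u. over a 100 a.u.
membrane sheet is rendered, detected, and quantified: the division-mode
C/P ratio is exactly 2.0, the generator's planted truth.

The same flow at analysis scale lives in `analysis/` (numbered
scripts). Running them in order prints, among other things:

```
noiseless: 6/6 cilia recovered, mean |rel err| = 0.0006
poisson:   6/6 cilia recovered, mean |rel err| = 0.0290
ciliation field: 9 cilia / 12 nuclei = 0.75
20 hits at FDR 0.1; sensitivity 1.00, observed FDR 0.00
mw_n4_complete_separation_p: 0.0286
```

i.e. on noiseless synthetic fields every planted cilium (and no
distractor) is recovered and the C/P ratios match truth to the 16-bit
quantization of the stored stack; under Poisson noise the mean relative
error stays under 5%; and the simulated bottom-10% screen (500 genes,
20 planted |2 SD| effects, 2×10⁶ reads, 10,000 permutations) recovers
every planted hit with no false positives at FDR 0.1.

A `ciliascreen` console command wraps the same operations
(`simulate`, `detect`, `quantify`, `screen-score`, `pathway`, `stats`)
with a YAML config and per-run manifest; see `ciliascreen --help`.

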