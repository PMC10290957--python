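# gutmap

Spatially resolved analysis of the gut metabolome along the mouse
intestine: absolute quantification of targeted LC–MS metabolite panels
via calibration curves with automatic linear-range selection, spatial
and differential description of the resulting concentration landscape,
microbial-origin inference from colonized (SPF) versus germ-free (GF)
comparisons, post-ASV 16S community processing, and a metabolite–microbe
association cascade. A synthetic study generator with planted ground
truth makes every stage testable end to end without instrument data.

It is written for metabolomics/microbiome researchers who have targeted
ion-count matrices, dilution-series standards, and ASV tables in hand
and want a tested, reproducible path from raw counts to origin calls and
producer-taxon candidates.

## The core procedures

**Calibration with iterative trimming.** For each metabolite and adduct
the dilution series (default: 24 two-fold steps from 150 µM down to
17.9 pM) is fitted by ordinary least squares of log₁₀(ion count) on
log₁₀(concentration), exhaustively removing up to 6 steps from the
concentrated end and up to 12 from the dilute end and keeping the window
that maximizes R². The lowest/highest retained steps define the LLOQ and
ULOL; sample values outside are censored, never extrapolated. In-range
concentrations are reported as nmol per mg sample (×2 injection
dilution, 20 µL/mg extraction). One adduct per metabolite is selected by
coverage, then R², then linear-range width; metabolites with R² < 0.99
fail QC.

**Differential and origin analysis.** Paired t-tests across mice with
Benjamini–Hochberg correction for habitat and region contrasts;
SPF/GF fold-change cascades; and the fourfold origin rule — large
intestine ≥ 4× small intestine, then SPF ≥ 4× GF within the large
intestine (SPF-exclusive compounds pass categorically), plus
subregion-specific calls within duodenum/jejunum/ileum.

**Association cascade.** Metabolites are classified host / microbe /
both / unmatched by intersecting their enzyme (EC) sets with the host
network and the predicted microbiome network; metabolite–taxon pairs are
scored by Spearman correlation over matched (mouse, region, habitat)
observations and filtered through the sequential funnel
P < 0.01 → SPF/GF fold change > 2 → enzyme possession → positive
correlation.

## Worked example

```python
from gutmap import StudyDesign, default_panel, run_study

study = run_study(panel=default_panel(seed=1), design=StudyDesign(), seed=1)

print("quantified:", study.quant.n_quantified)
oc = study.origin_calls
print("LI-enriched:", int(oc["stage1_li_enriched"].sum()))
print("microbially supported:", int(oc["stage2_spf_supported"].sum()))
print("origin classes:", study.origin_labels.value_counts().to_dict())
print(study.funnel.to_string(index=False))
```

prints

```
quantified: 128
LI-enriched: 31
microbially supported: 24
origin classes: {'both': 81, 'unmatched': 27, 'microbe': 13, 'host': 7}
    stage  n_pairs
all_pairs    15360
   p<0.01     3335
   fc>2.0     1134
   enzyme       33
    rho>0       19
```

Of 138 targeted metabolites, 128 pass calibration QC (the 10 planted
failures are rejected). The origin cascade recovers the 31 planted
large-intestine-enriched metabolites and labels exactly the 24 with a
planted ≥ 4-fold SPF/GF ratio as microbially supported; the enzyme
networks partition the panel 7/13/81/27. The association funnel reduces
the 128 × 120 metabolite–taxon pairs to 19, which include all 12 planted
producer taxa.

The same workflow is scriptable from the shell:

```sh
gutmap synth all --seed 1 --outdir demo/
gutmap quantify fit --standards demo/standards.csv --out demo/fits.tsv
gutmap micro filter --prefix demo/asv --out-prefix demo/kept
gutmap diff origin --spf demo/true_SPF --gf demo/true_GF --out demo/origin.tsv
```

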