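# zonequant

Depth-stratified quantification of DNA-damage (53BP1) and senescence (p16)
markers across the six radial zones of a cortical gray-matter column, together
with a synthetic-cortex generator that makes every stage of the analysis
verifiable against ground truth.

## The problem

Post-mortem studies of the aging and Alzheimer's disease (AD) cortex count
marker-positive cells in whole-slide immunofluorescence images: nuclei are
detected in the DAPI channel, each nucleus is expanded by 5 µm into an
artificial "pseudoplasm" annulus to sample perinuclear signal, cells are
classified 53BP1-positive by an intensity threshold, and positive fractions
are compared across six depth zones drawn between the pia mater (Zone 1) and
the white matter (Zone 6). The scientific questions are spatial: does the
fraction of damaged cells change with cortical depth, is the depth profile
linear or hump-shaped, and how tightly is nuclear p16 (senescence) coupled to
53BP1 (DNA damage) cell by cell?

`zonequant` implements that pipeline as a tested, reusable library for people
who want to run the same analysis on their own QuPath exports — or audit it.
Because no public dataset accompanies this kind of study, the package ships a
generator (`zonequant.synthcortex`) that simulates cortical tissue with the
relevant statistical structure, so detection, zonation and statistics can all
be validated against known truth.

## The model

Cells sit in a ribbon between the pia and the white matter. The probability
that a cell in zone *z* ∈ {1..6} carries DNA damage is

    p(z) = clip(a + b·z + c·z², 0, 1)

with defaults (a, b, c) = (0.0201, 0.0955, −0.010612) for AD — a parabola
with vertex at z = 4.5, peak 0.235 and zone-mean 0.1934 — and a flat
p(z) = 0.055 for unaffected controls (UC). Each case adds a random intercept
on the logit scale (sd 0.15). Nuclear areas come from a neuron/glia
log-normal mixture (mean 79 vs 28 µm²); 53BP1 intensity is log-normal with a
damage-dependent mean plus a shallow size slope κ·(area − mean area). For
damage-positive cells, nuclear p16 is linearly coupled to 53BP1 intensity
with noise scaled so that the asymptotic coefficient of determination is

    r² = 1 / (1 + ratio²)

where `ratio` defaults to 0.62 in AD (r² ≈ 0.72) and 1.60 in UC (r² ≈ 0.28).
The statistics layer (`zonequant.lamstats`) provides the depth-profile
linear/quadratic fits with adjusted r² = 1 − (1 − r²)(n − 1)/(n − k − 1), the
partial-F model comparison, condition × zone ANOVA (Type II), unpaired
t-tests, size-ranked intensity binning (100 cells/bin), and the 100-cells-
per-case marker-coupling regression. An etoposide-culture simulator covers
the companion in vitro experiment (γ-H2AX positivity rises with dose from 5%
to ~38%; p27 stays at 15%, independent of damage).

## Worked example

```python
import json
from zonequant import iface
from zonequant.synthcortex import GeneratorConfig

cfg = iface.PipelineConfig(seed=1)
cfg.uc = GeneratorConfig.for_condition("UC", cells_per_case=2000)
cfg.ad = GeneratorConfig.for_condition("AD", cells_per_case=2000)
iface.run_pipeline(cfg, "out")

report = json.loads(open("out/report.json").read())["results"]
print(report["fig4G"])
print({c: r["r2"] for c, r in report["fig6E"].items()})
```

prints (seed 1):

```
{'ad_mean_fraction': 0.1922, 'uc_mean_fraction': 0.0587, 't': 13.39, 'p': 4.2e-05}
{'AD': 0.746, 'UC': 0.325}
```

The first line is the condition comparison of overall damage fractions: about
19% of AD cells versus 6% of UC cells are 53BP1-positive in this cohort (a
3.3-fold difference, significant by unpaired t-test on case means). The
second line is the per-cell p16-on-53BP1 coupling r² from 100 sampled cells
per case: strong coupling in AD, weak in UC. The same report contains the
zone-profile fits (`fig5A_*`: the AD profile prefers the quadratic model),
the size-ranked intensity slopes (`fig5D`), the positive/negative-subset p16
depth profiles and ANOVA (`fig6B`–`fig6D`), and the etoposide culture
fractions (`fig7B`). A command-line interface mirrors the library:
`zonequant run --out out`, plus `simulate`, `detect`, `zonate`, `quantify`,
`analyze`, `culture`, `report` subcommands.

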