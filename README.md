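# zfsentinel

Wild zebrafish (*Danio rerio*) are cheap, widespread biological
sentinels: differences in how groups of fish shoal, move, and are
shaped can flag differences in water conditions between field sites
without laboratory assays.  `zfsentinel` is a Python implementation of
such a two-site sentinel protocol for researchers and field teams who
have (a) per-frame 2-D trajectories exported by video tracking of
6-fish groups and (b) 7-landmark TPS files digitized from dorsal
photographs.  It computes the protocol's endpoints, runs its
statistics, and can simulate entire synthetic studies with known
ground truth.

**Endpoints.** Social: inter-individual distance
(IID_i = mean_t mean_{j≠i} ||x_i(t) − x_j(t)||), nearest-neighbour
distance (min_{j≠i} instead of the mean), and time in proximity
(seconds with any neighbour within two body lengths, 1000 px by
default).  Activity: distance traveled, swim speed, time in motion,
and tank exploration (grid-cell area visited).  Morphometric: standard
length (mouth→caudal landmark), anterior (LM 1,5,6,7) and posterior
(LM 2,3,4,5) body-region shoelace areas and their ratio, and
generalized Procrustes analysis with shape PCA (relative warps,
uniform weighting).

**Statistics.** Welch t on tank means for behavior (the tank is the
independent unit); for shape: Pillai-trace MANOVA (Population × Sex,
Type II scatter matrices) on PC scores, two-way ANOVA + Tukey HSD on
the area ratio, exact Wilcoxon signed-rank (posterior vs anterior
areas), and tie-corrected Kruskal–Wallis on standard length.  See
`docs/methods.md` for models, defaults, and limitations.

## Worked example

Simulate the built-in two-site study preset and run both analysis
branches:

```bash
zfsentinel full --seed 1 --out out/
```

or in Python:

```python
from zfsentinel.pipeline import RunConfig, run_full

report = run_full(RunConfig(mode="synthetic", seed=1, out_dir="out"))
t = report["behavior"]["tests"]["swim_speed_mm_s"]
print(t["statistic"], t["p_value"], t["effect_direction"])
m = report["morphometrics"]
print(m["pc12_variance_pct"], m["tests"]["anova_Population:Sex"]["p_value"])
```

prints (seed 1):

```
397.33192340239856 7.392410618370684e-28 site1 > site2
71.96582427586988 0.007160407256587435
```

meaning: tank-mean swim speed differs overwhelmingly between sites
with site 1 faster (the preset plants 14 vs 9 mm/s, and tank means of
5400-frame averages have tiny spread, hence the enormous t); the
first two shape
principal components carry ~72% of shape variance; and the
Population × Sex interaction on the posterior/anterior area ratio is
significant at p ≈ 0.007 — the planted Site-2-only sex dimorphism
(male ratio ~1.3 vs ~1.5–1.6 elsewhere), which Tukey's test then
attributes to Site 2 males sitting below all other groups.  The run
writes tidy endpoint tables (`behavior_fish.tsv`, `behavior_tank.tsv`,
`morphometrics_fish.tsv`), aligned coordinates and PC scores, JSON
reports with a config hash for provenance, and consensus-shape and
boxplot figures.

Real data enter through the same door: `trajectory_files` entries
(`generic-csv` or `toxtrac` dialects) plus a `tps_file` with a sidecar
`fish_id/site/sex` table, with pixel-to-mm calibration in the config.
Tanks in which any fish was detected in fewer than 80% of frames are
excluded by the tracking-accuracy gate.

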