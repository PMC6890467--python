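# oricycle

Simulation and correlation-structure analysis of the *E. coli* cell
cycle, built around the replication-centric **double-adder** model of
cell-cycle control.

## The scientific problem

Proliferating bacteria must coordinate two cycles: the division cycle,
which sets cell size, and the chromosome-replication cycle, which sets
the number of origins (*oriC*). Mother-machine time-lapse experiments
give per-frame cell lengths and fluorescent-spot counts of replication
origins along single lineages, from which one can measure, for every
cell cycle, the sizes at birth, initiation and division, the durations
between those events, and the single-cell growth rate. Competing
phenomenological models — sizers (divide/initiate at a critical size),
timers (after a fixed duration) and adders (after adding a fixed
increment) — make different predictions about how these variables
*co-fluctuate* across cells, even when they predict the same averages.

`oricycle` implements the full in-silico counterpart of such a study:

* **simulator** — a stochastic per-origin lineage simulator of the
  double-adder model and three competitors (initiation timer,
  initiation sizer, uncoupled independent adders). In the double adder,
  replication initiation fires when the per-origin size
  `Λ(t) = L(t)/n_ori` has grown by a drawn increment `dΛif` since the
  last initiation, and the matching division fires at absolute length
  `Ld = n(Λi + dΛid)`. Growth is exponential with heritable rate
  fluctuations (mother-daughter correlation ≈ 0.3) and noisy division
  ratio.
* **synthetic_microscopy** — renders exact trajectories into
  mother-machine-style frame tables (3-min frames, multiplicative
  log-normal length noise, per-origin spot-detection failures, fusion
  of nearby spots), the same contract real segmentation/tracking
  produces.
* **cycle_extraction** — turns frame tables into division-centric
  (`Lb, Ld, Tbd, Li, Tbi, λ, dL, dLbi, Rbd, Rbi`) and
  replication-centric (`Λi, Λf, Λb, Tif, Tib, α, dΛif, dΛib, Rif, Rib`)
  cycle tables. Sizes come from exponential elongation fits; initiation
  times from the first persistent increase of the spot count; a QC
  filter removes incoherent origin tracks and poorly fitting cycles.
* **decomposition** — the model-selection framework. A *decomposition*
  is a minimal variable set (3 for the division cycle, 4 for the full
  cycle) from which all other variables follow through the algebraic
  relations (sums, growth ratios, `log(ratio) = rate × duration`). Each
  sufficient decomposition is scored by its independence

      I = det(R),

  the determinant of the Pearson correlation matrix of its variables
  (1 = fully independent fluctuations, 0 = a linear dependence), and all
  decompositions are ranked by `I`.
* **diagnostics** — binned scatters and the signed correlation tests
  that discriminate the models (e.g. `corr(Li, Lb) > 0` rejects a
  critical initiation mass; `corr(Tid, growth rate) < 0` rejects an
  initiation-to-division timer; `corr(dΛib, Λi) < 0` is the signature
  of uncoupled adders).
* **pipeline / CLI** — a deterministic end-to-end runner
  (simulate → render → extract → QC → decompose → diagnose) with YAML
  configuration; the `oricycle` command exposes each stage, so real
  tabular track data can be injected at the `extract` boundary.

## Worked example

```python
import oricycle as oc

params = oc.default_params("double_adder")   # 89-min doubling, slow growth
logs = oc.simulate_lineages(
    params, oc.SimConfig(n_lineages=100, duration=1800.0, seed=42)
)
frames = oc.render_frames(logs, oc.ObsConfig(seed=43))
division, _ = oc.qc_filter(oc.build_division_cycles(frames))
replication, rep_qc = oc.qc_filter(oc.build_replication_cycles(frames))
print(f"kept {rep_qc.n_kept}/{rep_qc.n_input} pseudo-cycles")

report = oc.rank_decompositions(
    replication, oc.get_pool("replication_centric_full")
)
print(report.to_text(3))
```

prints

```
kept 799/900 pseudo-cycles
Decomposition ranking — pool: replication_centric_full
rank  independence       n  variables
   1        0.9878     799  Lambda_i+alpha+dLif+dLib
   2        0.8576     799  Lambda_i+alpha+dLif+Rib
   3        0.8244     799  Lambda_b+Tib+alpha+dLif
```

The top decomposition `{Λi, α, dΛif, dΛib}` is exactly the set of
variables the double-adder model draws independently — the ranking
recovers the generative model from the noisy, frame-sampled data, with
an independence near the theoretical maximum of 1. Simulating the
initiation-timer variant instead puts a `Tib`-containing decomposition
first, i.e. the method identifies whichever control model produced the
data. The same pipeline run from the shell:

```bash
oricycle all --seed 42 --n-lineages 100 --out runs/demo
oricycle all --seed 42 --variant initiation_timer --out runs/timer
```

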