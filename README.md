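# titervision

Infectious titer determination for lentiviral vectors (LV) from live-cell
time-lapse imaging, plus the assay's quality-control and vector-stability
statistics, and a ground-truthed synthetic plate simulator.

## The problem

The functional (infectious) titer of a lentiviral vector — transducing units
per mL — is the number of particles able to transduce target cells. It can
be read out by real-time fluorescence imaging of a 96-well plate: HEK293T
cells are transduced with a serial dilution of the vector, transduced cells
expressing a surface receptor (e.g. an anti-CD19 CAR) are stained live with
a FabFluor-488-labelled antibody (green), dead cells with a cytotoxicity dye
(red), and every well is imaged every 2 h in phase contrast plus both
fluorescence channels. `titervision` implements the full analysis chain for
such an assay: image segmentation with the assay's operator settings,
per-well kinetic curves with peak readout selection, cell-count calibration,
titer computation, plate QC and stability statistics.

## The model

Per frame, binary masks give four areas: confluence `A_C` (phase contrast),
green-positive `A_FF488`, dead `A_D` (red), and the infected-but-dead
overlap `A_PD`. Fluorescence masks are built by the operator chain
*top-hat background subtraction (disc radius 20 µm) → intensity threshold
(1.3 GCU green / 0.3 RCU red) → clean-up (−1 px green / 0 px red) →
connected-component area filter (≥35 µm²; 35–1400 µm² red)*; the phase mask
uses a local-texture segmentation with a −2 px clean-up and a 170 µm²
minimum area. From the areas:

    P2 = A_FF488 / A_C × 100                       (percent positive, all cells)
    P3 = (A_FF488 − A_PD) / (A_C − A_D) × 100      (percent positive, viable cells)
    N  = (C − b) / m                               (cells from confluence C via a
                                                    linear calibration against an
                                                    offline cell count)
    titer [TU/mL] = P · N · D / (V · 100)

where `D` is the dilution factor and `V` the transduction volume in mL.
`P` is taken at the readout time — the maximum of the well's kinetic curve —
and only wells inside the assay's linear range (found on the dilution series
with per-subrange OLS fits) enter the sample mean.

QC statistics: replicate mean, sample SD, CV% = 100·SD/mean, and the
Z′-factor `1 − 3(σ_p + σ_n)/|µ_p − µ_n|`. Stability statistics:
percent-of-control infectivity, exponential half-life via log-linear OLS
(`t½ = ln 2 / λ`, delta-method SE), and peristaltic-pump pass counts
(`flow · duration / reservoir`, rounded half away from zero).

The simulator generates plates with known truth: logistic growth, a
single-hit Poisson dose–response (`MOI = titer·V/(D·N)`,
`P_inf = 1 − e^(−MOI)`), a rise-then-decay staining kinetic
`g(t) = (t/τ)^s e^{s(1−t/τ)}`, and rendered three-channel frames.

## Worked example

Simulate a plate at a known titer, measure it with the full pipeline
(segmentation of rendered frames, cell-count calibration, linear-range
detection, titer):

```python
from titervision import SimConfig
from titervision.pipeline import recover_plate_titer

res = recover_plate_titer(SimConfig(seed=7))   # 2e7 TU/mL, 1:2..1:1024, 6e3 cells
lr = res["linear_range"]
print(f"linear range 1:{lr.dilution_lo:.0f}-1:{lr.dilution_hi:.0f}, R^2 {lr.r_squared_linear:.3f}")
print(f"log-model R^2 {res['r_squared_log']:.3f} vs full-range linear {res['r_squared_linear_full']:.3f}")
print(f"recovered titer {res['recovered_titer']:.3g} TU/mL (truth {res['true_titer']:.3g})")
for s in res["sample_results"]:
    if s.n_wells_used:
        print(f"{s.sample_id:9s} n={s.n_wells_used} {s.titer_tu_per_ml:.3g} +/- {s.sd:.2g} TU/mL")
```

prints (about half a minute on one CPU):

```
linear range 1:128-1:1024, R^2 0.994
log-model R^2 0.863 vs full-range linear 0.300
recovered titer 1.61e+07 TU/mL (truth 2e+07)
LV_D1024  n=1 2.52e+07 +/- 0 TU/mL
LV_D128   n=2 1.35e+07 +/- 8.9e+05 TU/mL
LV_D256   n=3 1.58e+07 +/- 1.4e+06 TU/mL
LV_D512   n=3 1.78e+07 +/- 2.8e+06 TU/mL
```

The dose–response follows a logarithmic trend over the full dilution series
and is linear over the 1:128–1:1024 subrange; only wells whose peak
normalized positive area lies inside that range's detection limits enter
the sample means. The recovered titer sits somewhat below truth because
percent-positive saturates below the Poisson MOI at finite dilution — the
inherent bias of any percent-positive titration outside the low-MOI limit.

A shell workflow is available through the CLI:

```
titervision simulate --config sim.yaml --out plate/
titervision segment --images plate/frames --out areas.csv
titervision timecourse --areas areas.csv --out curves.csv
titervision calibrate --counts counts.csv --out calib.json
titervision titer --areas areas.csv --plate-map plate/plate_map.csv \
    --calibration calib.json --out titers.csv
titervision qc --values values.csv --negative-group neg --out qc.csv
titervision stability --data stress.csv --out stability.csv
```

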