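# scratchquant

Entropy-based quantification of scratch (wound-healing) assays, with the
companion plate-based calculations used alongside them: MTT growth-inhibition
levels (GI50/GI25/GI10), dual-color fluorescence ratios (AO/PI, JC-1, NAO)
and qPCR ΔΔCq fold changes. Written for cell-biology labs that photograph
scratched monolayers on a phase-contrast microscope and want a transparent,
deterministic alternative to hand-tracing wound outlines.

## How it works

A confluent monolayer is texture-rich; a cell-free scratch is flat. For each
pixel, the local Shannon entropy of the intensity histogram over a disk
neighborhood of radius *r* (the "disc size"),

    H = − Σ p_i log2 p_i   [bits],

is high over cells and near zero over the wound. The entropy map is rescaled
to 8 bits, thresholded (wound = below threshold), cleaned morphologically
(closing, then opening), and filtered by connected-component size; the wound
area is the union of the surviving components. Presets carry the per-cell-line
parameters (disc size, threshold): TOV-21G (20, 92) and SK-OV-3 (50, 92).
Closure kinetics are reported relative to the initial wound:

    open_pct(t) = 100 · wound_area(t) / wound_area(T0).

GI levels are obtained from the MTT viability formula
`100·(T − Tc)/(C − Cc)` (570 nm signal, 630 nm background) by linear
interpolation in log10(concentration); fold changes use
`2^(−ΔΔCq)` with HPRT1 as the default reference gene.

A synthetic-data module generates scratched-monolayer images, closure
series, 4PL dose-response plates and Cq tables with exact ground truth, and
backs the entire test suite.

## Worked example

Segment a simulated closing wound (30 % of a 2680×120 px frame, closing to
60 % and then 10 % of its initial width) and report closure relative to T0:

```python
import scratchquant as sq

spec = sq.ScratchSpec(height=120, width=2680, wound_frac=0.3, seed=5)
images, truths = sq.make_series(spec, (1.0, 0.6, 0.1), (0.0, 24.0, 48.0))

params = sq.SegmentationParams(disc_size=8, threshold=92)
tps = tuple((t, sq.segment_wound(img, params))
            for (t, _), img in zip(truths.timepoints, images))
res = sq.open_wound_percent(sq.ScratchSeries(well_id="demo", timepoints=tps))
for t, p, c in zip(res.times_h, res.open_pct, res.closure_pct):
    print(f"t={t:>4.0f} h   open {p:6.2f} %   closed {c:6.2f} %")
```

```
t=   0 h   open 100.00 %   closed   0.00 %
t=  24 h   open  59.16 %   closed  40.84 %
t=  48 h   open   8.15 %   closed  91.85 %
```

T0 is 100 % by definition; the 24 h and 48 h estimates land within ~1–2
points of the generator's true 60 % and 10 % — the residual comes from the
entropy transition zone at the wound edges (see `docs/methods.md`).

The same pipeline is available from the shell:

```
scratchquant segment --cell-line tov21g well3_24h.png --save-mask --out-dir out/
scratchquant series manifest.csv --disc-size 8 --out-dir out/
scratchquant gi plate.csv --out-dir out/
scratchquant qpcr cq.csv --reference-gene HPRT1 --out-dir out/
scratchquant synth --seed 1 --out-dir synth_out/
```

Every run writes a `run_manifest.json` (resolved configuration, package
version, seed) next to its CSV outputs.

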