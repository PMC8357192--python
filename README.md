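# flimcart

Fiber-based fluorescence lifetime imaging (FLIm) analysis of articular
cartilage, aimed at detecting glycosaminoglycan (GAG) loss — the earliest
biochemical marker of osteoarthritis — from label-free autofluorescence.

The package implements the full computational chain for cross-sectional
cartilage FLIm scans acquired with a temporally multiplexed, three-channel
fiber instrument (355-nm pulsed excitation, ~600 ps; detection bands
375–410, 450–485 and 530–565 nm routed through delay fibers onto one
detector):

1. **Demultiplexing** — slice each digitized record into three
   baseline-subtracted channel decays (`waveform`).
2. **Constrained Laguerre deconvolution** — expand the fluorescence
   impulse response on an orthonormal discrete Laguerre basis,
   `h = B c`, and solve

   `min_c ‖ irf ⊛ (B c) − y ‖²  subject to  (B c)_n ≥ 0`

   exactly, as a cone projection solved through its non-negative
   least-squares dual (`laguerre`).
3. **Parameter maps** — per pixel and channel, the average lifetime
   `τ̄ = Σ tₙ hₙ / Σ hₙ` (the expected photon arrival time of the
   area-normalized decay) and the intensity ratio
   `ρ_k = I_k / (I₁+I₂+I₃)` (`maps`).
4. **Geometry** — surface detection from the maximum axial intensity
   gradient, Euclidean distance-to-surface maps, and depth-resolved
   lifetime profiles (`geometry`).
5. **Segmentation** — the GAG-depleted superficial layer is the
   surface-contiguous run of pixels whose channel-1 intensity ratio is
   below 0.25 (a threshold re-derivable by ROC analysis); its per-column
   extent is the depletion thickness (`segment`), with one-way
   ANOVA/Tukey comparisons across treatment groups.

Because no instrument data are publicly available, the package ships a
first-class synthetic phantom generator (`phantom`) that emulates the
instrument and the tissue: a PBS buffer region above a tilted surface,
a channel-1 lifetime that rises from 5.7 ns superficially to 6.1 ns in
the deep zone within the first 0.5 mm, healthy channel-2/3 lifetimes of
6.34/5.22 ns, and — for the enzyme-treated presets — a 0.3 mm ("low") or
0.7 mm ("high") depleted layer with lifetimes shortened by 0.44/0.75 ns
and intensity ratios changed by −37%/−31%/+23%. Every scan comes with
pixel-level ground truth, standing in for the histology that validated
the real experiment.

## Worked example

```python
import flimcart as fc

cfg = fc.AcquisitionConfig(seed=2)                    # 50x50 px, 0.2 mm, 40 dB
scan, truth = fc.make_phantom(cfg, fc.preset("high"))  # 0.7 mm depleted layer
maps = fc.build_maps(scan)                             # deconvolve every pixel
surface = fc.detect_surface(maps)
seg = fc.segment_depletion(maps, surface, threshold=0.25)
roi = fc.roi_summary(maps, truth.depleted_mask)
print(f"mean depletion thickness: {seg.mean_thickness:.3f} mm")
print(f"depleted ROI ch2/ch3 lifetime: "
      f"{roi['mean_lt'][1]:.2f} / {roi['mean_lt'][2]:.2f} ns")
```

prints

```
mean depletion thickness: 0.700 mm
depleted ROI ch2/ch3 lifetime: 5.91 / 4.48 ns
```

i.e. the threshold segmentation recovers the generated 0.7-mm depleted
layer exactly, and the ROI lifetimes sit within a few hundredths of a
nanosecond of the depleted ground truth (6.34 − 0.44 = 5.90 ns and
5.22 − 0.75 = 4.47 ns).

The same pipeline is scriptable from the shell:

```sh
flimcart phantom --preset high --seed 4 --out scan.h5
flimcart run --in scan.h5 --out results/ --depth-profile
flimcart segment --in results/ --threshold 0.25
```

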