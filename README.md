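# gelswitch

Analysis pipeline for temperature-responsive collagen/elastin hydrogel
actuators: video-based gel-area tracking, transition-temperature and stroke
extraction, cyclic-actuation metrics, maximal-inscribed-circle pore-size
granulometry of confocal network images, and circular-dichroism (CD)
spectra processing — together with synthetic-data generators that give every
stage a known ground truth.

## The problem

Electron-beam-crosslinked collagen/elastin gels contract sharply when heated
through a transition temperature T_t that is tunable by the absorbed dose
(kGy). Characterizing such an actuator means answering four questions, each
with its own data type:

1. **When does it switch?** From a top-view video of the disk-shaped gel on
   a heating stage, the projected area A(t) is measured per frame (circle
   fit by a gradient method, or Otsu thresholding with white-pixel
   counting), smoothed by Gaussian convolution (σ = 50 samples at
   0.9 frames/s), and T_t is read off as the temperature of the most
   negative derivative dA/dT on the heating branch.
2. **How much does it move?** The stroke is the plateau-to-plateau area
   loss, s = (A₀ − A₁)/A₀; an isotropic-shrinkage volume equivalent
   1 − (1 − s)^{3/2} is reported alongside.
3. **Is it reversible?** Over a 28–42 °C, 20-cycle protocol with 5-min
   dwells, the per-cycle irreversible loss is 1 − A_cool(k+1)/A_cool(k)
   over consecutive cool-end dwells (mean ± sd), plus per-cycle amplitudes
   and inflection points.
4. **What happens to the network and the molecules?** Confocal images of the
   stained fibril network are decomposed into "pores": each pore is the
   largest circle fitting between segmented fibrils (greedy
   distance-transform decomposition, exhaustively cross-checked), and the
   modal pore size P_max is the argmax of a kernel density over pore radii.
   CD spectra (250→190 nm, 0.2 nm steps) are replicate-averaged,
   water-reference subtracted, HT-masked (< 600 V down to 195 nm), smoothed
   (σ = 10) and norm-normalized; band positions near 197/203/207/222 nm
   report coil, elastin Cotton effect, β-turn and collagen triple-helix
   content, and a gel spectrum is fit as a least-squares superposition of
   its component spectra.

The laboratory recordings behind these analyses are not public, so the
`synthetic` module generates all inputs with known truth: sigmoidal area
traces A(t) = A₀·r(t)·[1 − s·S((T − T_t)/w)] with per-cycle loss factor
r(t), rendered top-view videos with a calibration square, fibrous and
foam-like network images, and CD spectra as weighted sums of fixed basis
bands. Every estimator is validated by recovery against these truths.

## Worked example

```python
import gelswitch as g

profile = g.synthetic.make_temperature_profile("ramp", 30, 45, 0.04, sampling_dt=5)
truth = g.SyntheticTruth(T_t=40.0, stroke_area=0.8, width_w=0.7, seed=1)
trace, _ = g.synthetic.make_contraction_trace(profile, truth, noise_sd=0.005)
video = g.synthetic.render_contraction_frames(trace, pixel_size=0.02, seed=1)
aligned = g.imaging_io.align_temperature(video, profile)
measured = g.area_tracking.track_area(aligned, method="threshold", sigma=11)
result = g.transition.find_transition(measured)
print(result.T_t, result.stroke_area)      # 40.0 0.7995...
```

The rendered 151-frame video is tracked back to within one temperature
sample of the truth midpoint (40.0 °C) and recovers the 80 % area stroke.
The numbered drivers under `analysis/` run the same chain at scale; e.g.
`analysis/02_track_transitions.py` prints per dose:

```
60 kGy: T_t = 41.20 degC (truth 41.25), stroke = 79.2 % area / 90.5 % volume
...
dose response: slope -0.1740 degC/kGy, T_t 50->90 kGy: 43.0 -> 36.0 degC
```

and `analysis/04_pore_analysis.py` reports the modal pore size shrinking
`24.7 -> 15.3 um (ratio 0.62)` across a synthetic contraction series.

The `gelswitch` console command wraps the same stages
(`simulate | track | transition | cycles | pores | cd | run`), with a
YAML config for reproducible end-to-end runs and a manifest of output
hashes; defaults follow the study protocols (σ = 50 for traces, σ = 10 for
spectra, 0.9 frames/s, HT < 600 V until 195 nm).

## Layout

- `src/gelswitch/` — library: `synthetic`, `imaging_io`, `area_tracking`,
  `transition`, `pores`, `cd`, `cli`
- `analysis/` — numbered narrative drivers writing tables under `results/`
- `tests/` — pytest suite including property-based acceptance checks
- `docs/methods.md` — models, parameter choices and limitations
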