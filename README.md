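# pulsecam

Heart rate from ordinary video of skin — remote photoplethysmography
(rPPG) for researchers who want a contact-free pulse measurement from a
consumer webcam, with every processing stage open, parameterised and
testable.

Each heartbeat changes the blood volume in the skin's capillary bed, and
hemoglobin absorption makes the skin minutely darker with every pulse.
`pulsecam` recovers the beating rate from that modulation through seven
stages:

1. **Spatiotemporal cropping** — drop the first/last 3 s, fix a region of
   interest (manual box or injected face detector).
2. **Skin selection** — k-means (k = 4, ≤ 100 iterations) on the CIELAB
   (a, b) chromaticity, keeping the cluster dominating the ROI's center;
   or a manual hue–saturation wedge fixed on the first frame.
3. **Averaging + detrending** — mean of selected pixels per frame and
   RGB channel; slow drift removed by subtracting a zero-phase 6th-order
   Butterworth low-pass at 0.04 Hz.
4. **ICA** — stabilised FastICA (3 components, ≤ 2000 iterations)
   concentrates the pulse, which all channels share, into one component.
5. **FFT** — one-sided power spectra |X(f)|² on a BPM axis (BPM = Hz·60);
   spectral resolution 60·fs/n BPM.
6. **Spectral smoothing** — zero-phase 3rd-order Butterworth low-pass
   along the frequency axis (normalized cutoff 0.2) merges the
   drifting-heart-rate peak cluster into one maximum.
7. **Respiration rejection** — the highest smoothed peak across
   components wins, *unless* it lies below 90 BPM while a peak above
   90 BPM reaches ≥ 70 % of its height — then that above-cutoff peak is
   the heart rate (post-exercise breathing/movement otherwise hijacks
   the estimate).

A ground-truthed synthetic generator (`pulsecam.synth`) produces traces
and uncompressed AVI videos with known heart rate, respiration, drift and
sensor noise, so the whole pipeline is verified by parameter recovery —
no recorded human data needed. A report module computes the standardized
accuracy summary (Spearman ρ, |Δ| mean ± SD per condition, Bland–Altman
bias and limits of agreement, ROC-AUC separability with
separability % = 100·(2·AUC − 1)).

## Worked example

```python
from pulsecam import PipelineConfig, run_pipeline
from pulsecam.synth import SynthSpec, synth_video

spec = SynthSpec(hr_bpm=100.0, hr_amp=2.0, noise_sd=1.0, seed=5)
synth_video(spec, path="demo.avi")
result = run_pipeline("demo.avi", PipelineConfig(seed=5))
print(result.hr_bpm, result.component_index, result.respiration_rule_fired)
```

Running `python examples/01_estimate_from_video.py` prints:

```
true heart rate : 100.0 BPM
estimated       : 100.0 BPM
from component  : 2
respiration rule: not fired
```

The estimate lands within one spectral bin (2.5 BPM here: 24 s of 30 fps
video survive the temporal crop) of the truth. The respiration case
(`examples/03_respiration_rejection.py`) shows the rule earning its keep
— respiration at 30 BPM carries the most power, yet:

```
full pipeline              : 140.0 BPM (rule fired: True)
no-rejection ablation      : 30.0 BPM  <- fooled by breathing
```

Other examples: `02_skin_selection.py` (both skin masks at Jaccard 1.000
against the known skin region) and `04_benchmark_report.py` (batch
estimation of six videos: ρ = 1.000, |Δ| ≈ 1.5 BPM, rest-vs-exercise
AUC = 1.00).

A thin CLI wraps the same functions:

```sh
pulsecam estimate video.avi --roi 300,150,400,400 --skin auto --json out.json
pulsecam batch manifest.csv --out records.csv
pulsecam synth spec.toml --count 6
pulsecam report records.csv --group-by exercise
```

Ablation flags `--no-ica --no-lff --no-resp` switch off individual
stages for method comparisons.

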