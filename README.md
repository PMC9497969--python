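# fluorocad

Computer-aided, automatic target-to-background (T/B) quantification for
wide-field fluorescence endoscopy.

In fluorescence endoscopy of the esophagus, a topically applied fluorescent
probe binds to receptors overexpressed by Barrett's neoplasia, so early
cancers appear as patchy bright targets on dimmer tissue.  The clinically
validated indicator of a suspicious lesion is the **T/B ratio**

```
T/B = mean(I over target) / mean(I over 30-px background band around it)
```

computed from a segmentation of the fluorescence target.  Producing this
number automatically on video requires two things: rejecting the many
frames that show a normal esophagus or artifacts (saturation, dye pooling,
air bubbles, the mother endoscope), and segmenting the target on the frames
that remain.  `fluorocad` implements that two-step pipeline for researchers
developing molecular-probe endoscopy:

1. **Frame selection** — a small CNN (mobile- or xception-style backbone,
   global average pooling, two fully connected layers) scores each frame's
   probability of containing a suspicious bright lesion; rejected frames
   never reach the slower second step.
2. **Segmentation + T/B** — the fluorescence target of each selected frame
   is segmented and quantified.  Two segmenters are provided: a
   from-scratch **Chan-Vese** level-set minimizing the piecewise-constant
   energy `mu*Length + nu*Area + lambda1*SSD_in + lambda2*SSD_out` (the
   reference method, and the generator of *weak labels*), and trainable
   **UNet / BiSeNet** networks that learn from those Chan-Vese labels —
   so no pixel-level human annotation is ever needed, only frame-level
   diagnoses.

Because the clinical videos behind this design are not distributable, the
package ships a synthetic scanning-fiber-endoscopy frame simulator
(circular field of view, patchy lesions, all four artifact families, full
pixel ground truth) that makes every stage testable end to end; the
networks run on a small numpy autodiff engine included in the package, so
there is no deep-learning framework dependency.

## Worked example

Segment a simulated suspicious frame with Chan-Vese and quantify it:

```python
from fluorocad.simulate import SimConfig, generate_frame
from fluorocad.chanvese import ChanVeseParams, segment
from fluorocad.tbquant import tb_ratio
from fluorocad.metrics import iou

cfg = SimConfig(size=128, seed=42)
phantom = generate_frame(cfg, "suspicious")
gray = phantom.fluorescence()

mask = segment(gray, ChanVeseParams(), phantom.fov_mask)
res = tb_ratio(gray, mask, phantom.fov_mask, width=30)

print(f"segmentation IOU vs ground truth: {iou(mask, phantom.lesion_mask):.3f}")
print(f"T/B = {res.tb_ratio:.3f}  (target mean {res.t_mean:.3f} over "
      f"{res.n_target_px} px, background mean {res.b_mean:.3f} over "
      f"{res.n_band_px} px)")
print(f"planted T/B = {phantom.planted_tb:.3f}")
```

prints

```
segmentation IOU vs ground truth: 0.992
T/B = 2.167  (target mean 0.882 over 3927 px, background mean 0.407 over 7643 px)
planted T/B = 2.180
```

The level set recovers the planted lesion to IOU 0.99 and the measured
ratio matches the simulator's planted contrast to under 1%.  The same flow
is available from the shell — `fluorocad simulate`, `fluorocad chanvese`,
`fluorocad tb`, `fluorocad gen-labels`, `fluorocad train-classifier`,
`fluorocad train-segmenter`, `fluorocad run`, `fluorocad evaluate` — with
YAML configuration; see `fluorocad --help`.

Training the two networks and running the full gated pipeline
programmatically:

```python
from fluorocad import desk
from fluorocad.pipeline import run_cad, RunConfig

clf, hist, val = desk.train_desk_classifier(seed=1)       # ~2 min CPU
seg, *_ = desk.train_desk_segmenter(seed=1, labels="chanvese")
df = run_cad("frames_dir", clf, seg, RunConfig(target_size=96))
# df: source_id, prob, selected, mask_path, t_mean, b_mean, tb_ratio
```

`docs/methods.md` documents the models, parameters and numerical choices.

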