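# cytofocus

Semantic autofocus for whole-slide imaging of liquid-based cytology (LBC)
slides — with a built-in virtual scanner so the whole control loop runs on
your desk.

## The problem

ThinPrep-style LBC slides deposit cervical cells inside a 22 mm circle as a
thin but genuinely three-dimensional layer: focus heights vary smoothly by up
to ~30 µm across the circle. A general-purpose, contrast-based autofocus
cannot tell a cell from an artifact, and routinely locks onto dust on the
coverslip — a second, spurious focal plane. The usual workaround, z-stack
scanning at many focal planes, multiplies scan time and data volume.

`cytofocus` implements the alternative: **single-layer scanning with semantic
focus control**. Three cooperating pieces make it work:

1. **Focus-point validity filter.** Each autofocus probe image is accepted
   only if it shows in-focus cellular material: a segmented object at least
   the size of a small nucleus (200 px at 20×/0.46 µm px⁻¹), at least one
   Canny edge (high threshold 0.07, σ = 1.41 — blurred images have none), and
   at least 10 object pixels inside one of four stain HSV classes
   (hematoxylin nuclei, cytoplasm, DAB/p16 brown, Fast Red/Ki-67). Validity
   is the conjunction of the three.
2. **Slide sharpness score.** The scanned area is divided 4×4; per region up
   to 200 cells are detected (Otsu + HSV stain test) and each cell tile is
   classified in-focus/out-of-focus by an RBF-kernel SVM (σ = 1 on z-scored
   features) over five no-reference sharpness features: Canny edge count,
   RMS gradient, difference to an unsharp-masked copy, difference to a
   Gaussian-blurred copy, and a perceptual blur estimate. A region's score is
   its percent of in-focus cells; the slide score is the mean over
   cell-bearing regions, with ≥ 90 the pass mark.
3. **Iterative scan workflow.** Detect the cell circle from the slide's dark
   border marks, place 12 focus points, keep the valid ones (> 5 required,
   else escalate the point count, five tries per attempt, two restarts),
   interpolate a focus map, scan, score, and refocus failing regions — up to
   seven scan rounds, after which the slide is declared not scannable.

Because the original slide imagery is not public, the package ships a
**virtual scanner**: synthetic slides with a known focal surface, stain
palette, dust plane and defocus optics (Gaussian blur growing linearly in
focal error), so every component is testable against ground truth.

## A worked example

```python
import cytofocus as cf
from cytofocus.sharpness import train_model
from cytofocus.workflow import VirtualScanner, WorkflowConfig, run_workflow

model = train_model(cf.make_training_set(150, seed=1), seed=1)
slide = cf.make_virtual_slide(width_um=1000, height_um=1000, n_cells=400, seed=5)
session = run_workflow(VirtualScanner(slide, seed=11), model, WorkflowConfig(seed=21))
print(session.status, session.final_score, session.scan_rounds)
```

prints

```
completed 98.4... 1
```

meaning: the first focus round produced 12 valid points, the resulting
focus map captured 98.4 % of sampled cells in focus — above the 90 % pass
mark — so one scan round sufficed. A five-cell slide instead runs out of its
focus-attempt budget and ends `not_scannable` (`examples/04` shows both).

The `examples/` directory holds one short narrative script per capability:
slide generation, focus-point filtering, sharpness training/scoring, the
scan loop, and the z-profile analysis. A thin CLI mirrors the same
operations:

```bash
cytofocus generate slide --seed 1 --out scratch/slide
cytofocus simulate-scan --seed 3 --session-log session.json
cytofocus metrics --table 1086 21 11 1177
```

## Layout

| module | what it owns |
|---|---|
| `cytofocus.synthetic` | virtual slides, defocus optics, strips, training sets |
| `cytofocus.focus_filters` | size / edge / color validity filters |
| `cytofocus.sharpness` | features, SVM, region and slide scoring |
| `cytofocus.workflow` | circle detection, focus maps, the scan loop, repeat-scan CV |
| `cytofocus.zprofile` | layer separation and z statistics |
| `cytofocus.metrics` | contingency-table metrics, coefficient of variation |
| `cytofocus.config` / `cytofocus.cli` | YAML run configuration and the `cytofocus` command |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
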