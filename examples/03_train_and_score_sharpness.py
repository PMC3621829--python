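"""Train the cell-focus SVM and score a scanned slide's sharpness.

Five no-reference features (Canny edge count, RMS gradient, difference
to an unsharp-masked copy, difference to a blurred copy, and a
perceptual blur estimate) feed an RBF-kernel SVM that labels each cell
in-focus or out-of-focus.  The slide is split into 16 regions; a
region's score is its percentage of in-focus cells and the slide score
is the mean over cell-bearing regions.
"""

import cytofocus as cf
from cytofocus.sharpness import score_slide, train_model
from cytofocus.workflow import ScannedSlide

model = train_model(cf.make_training_set(150, seed=1), seed=1)
print(f"trained on 300 cells, training accuracy "
      f"{100 * model.training_accuracy:.1f}%")

slide = cf.make_virtual_slide(width_um=1000, height_um=1000, n_cells=400,
                              seed=5)

for label, offset in [("scan at the true surface", 0.0),
                      ("scan 10 um off the surface", 10.0)]:
    scanned = ScannedSlide(slide, lambda x, y: slide.surface(x, y) + offset)
    report = score_slide(scanned, model, seed=0)
    print(f"\n{label}:")
    print(f"  slide score: {report.slide_score:.1f}% in-focus cells "
          f"({sum(report.cells_examined)} cells examined)")
    print(f"  regions below 90%: {report.out_of_focus_regions}")
print("\nA slide passes when its score reaches 90%; failing regions are "
      "the ones the workflow refocuses.")
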