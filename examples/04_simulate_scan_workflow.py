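"""Run the full iterative single-layer scan loop against the simulator.

The loop: detect the cell circle on the macro image, place 12 focus
points, keep the semantically valid ones (more than five are required),
interpolate them into a focus map, scan, score sharpness, and refocus
failing regions until the slide passes 90% or seven scan rounds are
exhausted.
"""

import cytofocus as cf
from cytofocus.sharpness import train_model
from cytofocus.workflow import VirtualScanner, WorkflowConfig, run_workflow

model = train_model(cf.make_training_set(150, seed=1), seed=1)

for label, kwargs in [
        ("well-populated slide", dict(width_um=1000, height_um=1000,
                                      n_cells=400, seed=5)),
        ("nearly empty slide (5 cells)", dict(n_cells=5, seed=6))]:
    slide = cf.make_virtual_slide(**kwargs)
    scanner = VirtualScanner(slide, seed=11)
    session = run_workflow(scanner, model, WorkflowConfig(seed=21))
    print(f"\n{label}:")
    print(f"  status: {session.status}")
    print(f"  focus iterations: {session.focus_iterations}, "
          f"scan rounds: {session.scan_rounds}")
    for i, rnd in enumerate(session.per_round, 1):
        print(f"  round {i}: {rnd.n_valid} valid points, "
              f"score {rnd.slide_score:.1f}%, refocused {rnd.refocused_regions}")
    if session.final_score is not None:
        print(f"  final score: {session.final_score:.1f}%")
print("\nA slide completes once its score reaches 90%; slides whose focus "
      "never succeeds are declared not scannable, as happens for nearly "
      "empty preparations.")
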