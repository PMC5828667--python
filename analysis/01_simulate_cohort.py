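"""Simulate the synthetic two-group study inputs.

Writes the run configuration, the ground-truth hub networks for each
group, and the gaze dataset (reference clouds + deviating test tracks)
under results/cohort/. The test group's hub drives six regions against
the reference group's two; gaze deviations are drawn per test subject.
"""

from pathlib import Path

import numpy as np

from pdcflow import io as pio
from pdcflow.pipeline import DEFAULT_CONFIG
from pdcflow.synthetic import hub_network, simulate_gaze_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
OUT.mkdir(parents=True, exist_ok=True)

cfg = dict(DEFAULT_CONFIG)
chash = pio.write_config(OUT / "config.yaml", cfg)
print(f"config written (hash {chash}): {cfg['n_test']} test vs "
      f"{cfg['n_reference']} reference subjects, {cfg['n_epochs']} x 1-s "
      f"epochs at {cfg['fs']} Hz")

for group, n_targets in [("test", cfg["hub_targets_test"]),
                         ("reference", cfg["hub_targets_reference"])]:
    net = hub_network(cfg["n_rois"], hub=cfg["hub_roi"],
                      targets=list(range(1, n_targets + 1)),
                      strength=cfg["hub_strength"])
    net.to_json(OUT / f"network_{group}.json")
    print(f"{group}: hub ROI{cfg['hub_roi']:02d} drives {n_targets} regions "
          f"at strength {cfg['hub_strength']}")

rng = np.random.default_rng(cfg["seed"])
deltas = cfg["gaze_deviation_scale"] * rng.random(cfg["n_test"])
gaze = simulate_gaze_dataset(
    n_td=cfg["gaze_n_reference"],
    n_test=cfg["n_test"],
    n_frames=cfg["gaze_frames"],
    deviation=deltas,
    seed=cfg["seed"] + 501,
)
pio.write_gaze_tsv(OUT / "gaze.tsv", gaze)
print(f"gaze: {gaze.n_frames} frames, {gaze.n_reference} reference subjects, "
      f"test deviations {np.round(deltas, 2)}")
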