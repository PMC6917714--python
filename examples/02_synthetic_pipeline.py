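"""Full pipeline on a synthetic panel with planted ground truth.

Generates a 9-genome panel (3 metabolic clades, 12 planted gene-cluster
families, two spo0B deletions), runs every stage — reaction matrix,
clustering + binomial enrichment, SMGC families + co-localization, trait
profiles, tree concordance — and prints the stage-by-stage recovery of the
planted signals (1.0 = everything planted was found, nothing spurious).
"""

import json
import tempfile
from pathlib import Path

from bacpanel import SimulationConfig, Thresholds, run_all, simulate_panel

with tempfile.TemporaryDirectory() as td:
    panel_dir = Path(td) / "panel"
    simulate_panel(SimulationConfig.small(seed=1), panel_dir)
    result = run_all(panel_dir, Path(td) / "out", Thresholds(k_clades=3))

print("planted-signal recovery:")
print(json.dumps(result.recovery, indent=2))
print("\nSMGC family census:", json.dumps(result.census, indent=2))
print("\nclade vs tree monophyly:", result.concordance)
print("(clades 2 and 3 are planted as phylogenetically discordant —")
print(" metabolic similarity without shared ancestry, i.e. convergence)")
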