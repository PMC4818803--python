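"""Shared paths and study settings for the numbered analysis scripts.

Large intermediates (tag BEDs, per-window tables) go under scratch/, small
human-readable summaries under results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 0  # canonical study seed

SIM_DIR = SCRATCH / "sim"
PEAKS_DIR = SCRATCH / "peaks"
DIFF_DIR = SCRATCH / "differential"


def ensure_dirs() -> None:
    for d in (SIM_DIR, PEAKS_DIR, DIFF_DIR, RESULTS):
        d.mkdir(parents=True, exist_ok=True)
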