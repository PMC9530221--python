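"""Shared paths and parameters for the numbered analysis drivers.

Bulk intermediate data (per-scan TSVs) lives under scratch/; the tables and
summaries each step reports live under results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

SEED = 20260930
K = 4
N_SUBJECTS = 15
N_REGIONS = 200
FRAMES = 220
TR = 2.0
T_HORIZON = 1.0
N_SPINS = 200


def ensure_dirs():
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def require(path: Path, producer: str):
    if not path.exists():
        raise SystemExit(f"missing {path}; run {producer} first")
    return path
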