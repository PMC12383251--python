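"""Shared configuration for the numbered analysis scripts.

The scripts walk through a two-regime synthetic study: a low-hunting regime
with long-distance (elephant-type) seed dispersal and high seed immigration,
and a high-hunting regime where dispersal is gravity-like and local.  Every
step reads its input from and writes its tables to ``results/``.
"""

from pathlib import Path

from seeddisp.pipeline import RegimeConfig, StudyConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

SEED = 20260927

CONFIG = StudyConfig(
    seed=SEED,
    n_small_saplings=150,
    n_large_saplings=150,
    n_perm=999,       # permutations for the FSGS tests in script 04
    n_sim=99,         # Monte Carlo envelope simulations in script 03
    nm_starts=4,
    regimes=[
        RegimeConfig("low_hunting", m_s=0.8, delta_s=1000.0),
        # gravity-like dispersal and a suppressed recruit cohort
        RegimeConfig("high_hunting", m_s=0.05, delta_s=30.0,
                     n_small_saplings=80),
    ],
)

COHORTS = ("adult", "small_sapling", "large_sapling")


def regime_dir(name: str) -> Path:
    d = DATA / name
    d.mkdir(parents=True, exist_ok=True)
    return d
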