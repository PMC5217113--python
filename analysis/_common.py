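"""Shared setup for the numbered analysis scripts.

The simulated screens live under scratch/ (regenerated on demand, fully
determined by the seeds below); small summary tables go to results/.
"""

from pathlib import Path

from shscreen import simulate_screen
from shscreen.io import load_screen_counts, write_screen
from shscreen.library import load_manifest
from shscreen.simulate import make_graded_config, make_pilot_like_config

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

PILOT_SEED = 11      # pilot-like screen: 119 constructs, 17+8 control genes
GRADED_SEED = 11     # graded-effect screen for effect-size resolution
ANALYSIS_SEED = 7    # resampling analyses (subsets, thinning draws)


def pilot_screen_dir() -> Path:
    """The simulated pilot-like screen directory, generated if absent."""
    d = SCRATCH / "pilot_screen"
    if not (d / "input_pool.tsv").exists():
        write_screen(simulate_screen(make_pilot_like_config(seed=PILOT_SEED)), d)
    return d


def load_pilot():
    d = pilot_screen_dir()
    manifest = load_manifest(d / "manifest.tsv")
    input_pool, groups = load_screen_counts(d)
    return manifest, input_pool, groups


def graded_screen():
    cfg = make_graded_config(seed=GRADED_SEED)
    screen = simulate_screen(cfg)
    groups = {b: screen.tables_for_bio_rep(b) for b in screen.bio_rep_ids}
    return cfg, screen, groups
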