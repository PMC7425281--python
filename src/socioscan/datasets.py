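"""Published reference statistics for the five-school-class study.

These are the wave-1 ground-truth (nomination-based) network summary
values reported for the five Dutch school classes (A–E, directed and
undirected variants) of the MyMovez proximity study.  They are kept
here as reference points for calibration checks — e.g. the mean GT
density across the ten class networks, which the study quotes as 0.62
when contrasting close-knit classroom networks with sparse large-scale
cohorts.
"""

from __future__ import annotations

__all__ = ["W1_GT_DENSITY", "W1_GT_MEAN_DENSITY", "W1_CLASS_SIZES"]

#: Wave-1 GT network density per (class, connection type).
W1_GT_DENSITY: dict[tuple[str, str], float] = {
    ("A", "directed"): 0.50,
    ("A", "undirected"): 0.68,
    ("B", "directed"): 0.45,
    ("B", "undirected"): 0.60,
    ("C", "directed"): 0.56,
    ("C", "undirected"): 0.77,
    ("D", "directed"): 0.46,
    ("D", "undirected"): 0.64,
    ("E", "directed"): 0.70,
    ("E", "undirected"): 0.85,
}

#: The quoted average classroom GT density (wave 1, all ten networks).
W1_GT_MEAN_DENSITY: float = 0.62

#: Participating nodes per class (wave 1).
W1_CLASS_SIZES: dict[str, int] = {"A": 15, "B": 20, "C": 19, "D": 13, "E": 13}
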