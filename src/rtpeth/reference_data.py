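"""Bundled records from the validation study, used as report inputs.

``CONCORDANCE_SESSIONS`` holds the per-session counts from an
18-session chronic recording series in which 8 moveable tetrodes (144
tetrode recordings in total) were classified as light-responsive or
not, once online during the experiment and once by post-hoc offline
analysis.  Columns: online-positive count, offline-positive count,
true positives, false positives, false negatives, true negatives.

``ANIMAL_EXPERIMENT_HOURS`` holds the per-animal waiting-plus-recording
durations (hours, surgery excluded) of 12 acute recording experiments
that used online feedback to skip unresponsive electrode positions.
"""

from __future__ import annotations

# (session, online_pos, offline_pos, tp, fp, fn, tn)
CONCORDANCE_SESSIONS: list[tuple[int, int, int, int, int, int, int]] = [
    (1, 3, 2, 2, 1, 0, 5),
    (2, 3, 3, 3, 0, 0, 5),
    (3, 4, 2, 2, 2, 0, 4),
    (4, 8, 7, 7, 1, 0, 0),
    (5, 0, 1, 0, 0, 1, 7),
    (6, 2, 2, 2, 0, 0, 6),
    (7, 1, 1, 1, 0, 0, 7),
    (8, 3, 2, 2, 1, 0, 5),
    (9, 2, 2, 2, 0, 0, 6),
    (10, 2, 2, 2, 0, 0, 6),
    (11, 4, 4, 4, 0, 0, 4),
    (12, 5, 4, 4, 1, 0, 3),
    (13, 2, 2, 2, 0, 0, 6),
    (14, 1, 2, 1, 0, 1, 6),
    (15, 1, 0, 0, 1, 0, 7),
    (16, 1, 1, 1, 0, 0, 7),
    (17, 2, 0, 0, 2, 0, 6),
    (18, 2, 2, 2, 0, 0, 6),
]

TETRODES_PER_SESSION = 8

ANIMAL_EXPERIMENT_HOURS: dict[str, float] = {
    "PV-Cre 1": 7.5,
    "PV-Cre 2": 5.25,
    "PV-Cre 3": 5.25,
    "VGat-Cre 1": 6.0,
    "VGat-Cre 2": 4.5,
    "VGat-Cre 3": 3.75,
    "VGlut-Cre 1": 5.25,
    "VGlut-Cre 2": 5.25,
    "VGlut-Cre 3": 3.75,
    "ChAT-Cre 1": 4.5,
    "ChAT-Cre 2": 3.75,
    "ChAT-Cre 3": 3.75,
}
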