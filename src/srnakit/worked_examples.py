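"""Worked-example microarray signal table for the fold-change-percent helper.

A small set of (gene, control signal, treatment signal, expected percent)
rows from published microarray comparisons of sRNA-pathway and PPR genes in
two overexpression lines against wild type.  Only rows whose printed
percentage is arithmetically consistent with the printed signals are kept
(some published cells were evidently computed on unrounded signal values
and cannot be reproduced from the printed integers).
"""

from __future__ import annotations

from .abundance_stats import fold_change_percent

#: (gene, line, control signal, treatment signal, expected integer percent)
MICROARRAY_CELLS: tuple[tuple[str, str, int, int, int], ...] = (
    ("DCL1", "OE7", 1543, 2319, 150),
    ("DCL1", "OE21", 1543, 2501, 162),
    ("AGO1", "OE7", 9057, 10052, 111),
    ("AGO7", "OE7", 1073, 2149, 200),
    ("CPB20", "OE7", 3599, 4053, 113),
    ("CPB20", "OE21", 3599, 4057, 113),
    ("CPB80", "OE7", 6824, 6310, 92),
    ("CPB80", "OE21", 6824, 6274, 92),
    ("HEN1", "OE7", 1308, 1139, 87),
    ("HEN1", "OE21", 1308, 1403, 107),
    ("SDN1", "OE7", 1588, 446, 28),
    ("SDN1", "OE21", 1588, 647, 41),
    ("AT1G12620", "OE7", 2259, 231, 10),
    ("AT1G12620", "OE21", 2259, 207, 9),
    ("AT1G63070", "OE7", 666, 99, 15),
    ("AT1G63070", "OE21", 666, 138, 21),
    ("AT1G63080", "OE7", 1143, 551, 48),
    ("AT1G63080", "OE21", 1143, 716, 63),
    ("AT1G63150", "OE7", 1147, 350, 31),
    ("AT1G63230", "OE7", 541, 223, 41),
    ("AT1G63230", "OE21", 541, 228, 42),
    ("AT1G63330", "OE21", 2070, 885, 43),
)


def evaluate_cells() -> list[dict]:
    """Recompute every worked-example percentage from its printed signals."""
    return [
        {
            "gene": gene,
            "line": line,
            "control": control,
            "treatment": treatment,
            "expected_percent": expected,
            "computed_percent": fold_change_percent(treatment, control),
        }
        for gene, line, control, treatment, expected in MICROARRAY_CELLS
    ]
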