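"""Published reference tables of the GEMM classification study.

These are the printed decision-rule inputs of the original cross-species
analysis: the per-dataset GSA p-values for every mouse class against every
human subtype (three human cohorts: UNC308, Combined855, TCGA547), the
class membership fractions of each mouse model, and a handful of headline
count ratios. They serve as worked-example inputs: feeding them through
the pipeline's counterpart rule, homogeneity rule, and reporting
arithmetic must reproduce the published calls.

Dashes and "NA" in the GSA table mean the comparison was not reported
(p > 0.5 by the reporting convention) and count as non-significant;
"<1e-4" style entries are encoded at their bound.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .classes import (HETEROGENEOUS, HOMOGENEOUS, INSUFFICIENT_N,
                      SEMI_HOMOGENEOUS, categorize_shares)
from .cross_species import CounterpartTable, call_counterparts

HUMAN_SUBTYPES = ("Basal-like", "Claudin-low", "HER2-enriched",
                  "Luminal A", "Luminal B", "Normal-like")
HUMAN_DATASETS = ("UNC308", "Combined855", "TCGA547")

# per mouse class: 18 printed p-value cells, ordered subtype-major
# (Basal-like U,C,T; Claudin-low U,C,T; ...; Normal-like U,C,T)
GSA_TABLE: dict[str, list[str]] = {
    "WapINT3":         ["0.06", "0.09", "0.17", "-", "-", "NA", "-", "-", "-",
                        "-", "0.44", "-", "0.40", "0.34", "0.29", "-", "-", "-"],
    "Erbb2-like":      ["0.33", "0.30", "0.33", "-", "-", "NA", "<1e-4", "0.01", "0.01",
                        "0.31", "-", "-", "0.44", "0.40", "0.30", "-", "-", "-"],
    "Class3":          ["-", "-", "-", "0.46", "-", "NA", "0.41", "0.17", "0.38",
                        "0.31", "0.28", "0.34", "-", "-", "-", "0.12", "0.14", "0.29"],
    "Myc":             ["0.02", "0.01", "0.03", "-", "-", "NA", "0.22", "0.11", "0.07",
                        "-", "-", "-", "0.06", "0.01", "0.02", "-", "-", "-"],
    "PyMT":            ["0.41", "0.38", "-", "-", "-", "NA", "0.28", "0.09", "0.08",
                        "0.08", "0.33", "0.46", "0.02", "0.10", "0.12", "-", "-", "-"],
    "Neu":             ["-", "-", "-", "-", "-", "NA", "0.44", "0.36", "0.42",
                        "<1e-4", "0.01", "0.02", "0.10", "0.36", "0.43", "-", "-", "-"],
    "Normal-like":     ["-", "-", "-", "0.14", "0.21", "NA", "-", "-", "-",
                        "-", "0.07", "0.11", "-", "-", "-", "<1e-4", "0.01", "5e-4"],
    "Class8":          ["-", "-", "-", "0.09", "0.06", "NA", "0.48", "-", "-",
                        "0.40", "0.46", "0.11", "-", "-", "-", "0.28", "0.25", "0.26"],
    "Wnt1-Late":       ["0.37", "-", "-", "-", "-", "NA", "-", "-", "-",
                        "0.40", "0.41", "0.42", "-", "0.46", "0.40", "0.15", "0.01", "0.21"],
    "Wnt1-Early":      ["0.29", "-", "-", "-", "-", "NA", "-", "-", "-",
                        "0.40", "0.19", "0.33", "0.38", "0.40", "0.49", "0.39", "0.08", "0.21"],
    "p53null-Basal":   ["0.04", "0.05", "0.06", "-", "-", "NA", "-", "-", "0.16",
                        "-", "-", "-", "0.48", "0.29", "0.20", "-", "-", "-"],
    "Squamous-like":   ["-", "-", "0.35", "0.11", "0.02", "NA", "0.20", "-", "-",
                        "-", "-", "-", "-", "-", "-", "0.18", "0.09", "0.10"],
    "Stat1":           ["-", "-", "-", "0.37", "0.32", "NA", "0.07", "-", "-",
                        "0.31", "0.30", "0.16", "-", "0.48", "0.41", "0.38", "0.39", "-"],
    "Class14":         ["-", "-", "-", "0.35", "0.22", "NA", "-", "-", "-",
                        "0.17", "0.14", "0.01", "0.45", "-", "0.11", "0.06", "<1e-4", "0.04"],
    "C3Tag":           ["0.02", "0.02", "0.03", "0.38", "-", "NA", "-", "-", "0.24",
                        "-", "-", "-", "0.28", "0.12", "0.02", "-", "-", "-"],
    "Claudin-low":     ["-", "-", "0.38", "5e-4", "<1e-4", "NA", "-", "-", "-",
                        "-", "-", "0.20", "-", "-", "0.41", "-", "-", "0.17"],
    "p53null-Luminal": ["0.17", "0.07", "0.02", "-", "-", "NA", "0.35", "0.23", "0.15",
                        "-", "-", "-", "0.24", "0.24", "0.16", "-", "-", "-"],
}

#: the published predicted-counterpart column (empty list = no counterpart)
PUBLISHED_COUNTERPARTS: dict[str, list[str]] = {
    "WapINT3": [], "Erbb2-like": ["HER2-enriched"], "Class3": [],
    "Myc": ["Basal-like", "Luminal B"], "PyMT": [], "Neu": ["Luminal A"],
    "Normal-like": ["Normal-like"], "Class8": [], "Wnt1-Late": [],
    "Wnt1-Early": [], "p53null-Basal": ["Basal-like"], "Squamous-like": [],
    "Stat1": [], "Class14": ["Normal-like"], "C3Tag": ["Basal-like"],
    "Claudin-low": ["Claudin-low"], "p53null-Luminal": [],
}


def parse_printed_p(cell: str) -> float:
    """A printed p cell: dash/NA = untested (NaN); '<x' = its bound."""
    cell = cell.strip()
    if cell in ("-", "NA", ""):
        return math.nan
    if cell.startswith("<"):
        return float(cell[1:])
    return float(cell)


def printed_pvalue_frames() -> dict[str, pd.DataFrame]:
    """The printed GSA table as one class x subtype frame per human dataset."""
    frames = {}
    for d, ds in enumerate(HUMAN_DATASETS):
        rows = {}
        for cls, cells in GSA_TABLE.items():
            rows[cls] = [parse_printed_p(cells[3 * s + d])
                         for s in range(len(HUMAN_SUBTYPES))]
        frames[ds] = pd.DataFrame.from_dict(rows, orient="index",
                                            columns=list(HUMAN_SUBTYPES))
    return frames


def counterparts_from_printed(config: PipelineConfig | None = None) -> CounterpartTable:
    """Apply the replication rule to the printed per-dataset p-values."""
    return call_counterparts(printed_pvalue_frames(), config or PipelineConfig())


# ---------------------------------------------------------------------------
# model membership fractions and the 80% taxonomy
# ---------------------------------------------------------------------------

#: per model: (n tumors, [(class, count), ...] as printed, number of
#: additional unnamed classes ("k others"; None = not stated), printed label)
MODEL_MEMBERSHIP: dict[str, tuple[int, list[tuple[str, int]], int | None, str]] = {
    "Brg1-het":                 (12, [("Squamous-like", 4), ("Erbb2-like", 3)], 3, HETEROGENEOUS),
    "Normal mammary-lactating": (2, [("Normal-like", 2)], 0, HOMOGENEOUS),
    "p18-null":                 (9, [("Erbb2-like", 5), ("Normal-like", 2),
                                     ("Squamous-like", 1)], 0, HETEROGENEOUS),
    "Pik3ca-H1047R":            (12, [("Class14", 5), ("Squamous-like", 5)], 2, SEMI_HOMOGENEOUS),
    "Rb-null":                  (10, [("Erbb2-like", 4), ("Neu", 1)], 3, HETEROGENEOUS),
    "Stat1-null":               (7, [("Stat1", 7)], 0, HOMOGENEOUS),
    "TgMMTV-Aib1":              (9, [("Erbb2-like", 4), ("Myc", 2)], 2, HETEROGENEOUS),
    "TgMMTV-Atx":               (5, [("Class14", 3), ("Squamous-like", 1)], 1, SEMI_HOMOGENEOUS),
    "TgMMTV-Fgf3":              (5, [("Erbb2-like", 2), ("Normal-like", 2),
                                     ("Wnt1-Late", 1)], 0, SEMI_HOMOGENEOUS),
    "TgMMTV-Hras":              (8, [("Neu", 5), ("Class8", 2)], 0, SEMI_HOMOGENEOUS),
    "TgMMTV-Lpa":               (15, [("Normal-like", 6), ("Claudin-low", 3)], 3, HETEROGENEOUS),
    "TgMMTV-Myc":               (5, [("Myc", 4), ("Class8", 1)], 0, HOMOGENEOUS),
    "TgMMTV-Wnt1-iFgfr":        (12, [("Wnt1-Early", 7)], None, HOMOGENEOUS),
    "TgWAPCre-Etv6":            (12, [("Erbb2-like", 12)], 0, HOMOGENEOUS),
    "Brca1-Trp53-irradiated":   (7, [("p53null-Basal", 6), ("Wnt1-Early", 1)], 0, HOMOGENEOUS),
    "DMBA-induced":             (11, [("Squamous-like", 4), ("Claudin-low", 3)], 3, HETEROGENEOUS),
    "Normal mammary":           (16, [("Normal-like", 16)], 0, HOMOGENEOUS),
    "TgC3(1)-Tag":              (30, [("C3Tag", 28), ("Claudin-low", 2)], 0, HOMOGENEOUS),
    "TgMMTV-Cre-Brca1-Trp53":   (10, [("p53null-Basal", 4), ("Claudin-low", 3)], 1, HETEROGENEOUS),
    "TgMMTV-Neu":               (28, [("Neu", 25), ("Normal-like", 2)], 1, HOMOGENEOUS),
    "TgMMTV-PyMT":              (17, [("PyMT", 9), ("Class3", 1)], 0, HOMOGENEOUS),
    "TgMMTV-Wnt1":              (25, [("Wnt1-Early", 15), ("Wnt1-Late", 7)], 3, SEMI_HOMOGENEOUS),
    "TgWAP-Int3":               (7, [("WapINT3", 6), ("Class3", 1)], 0, HOMOGENEOUS),
    "TgWAP-Myc":                (21, [("Myc", 18), ("Class8", 3)], 0, HOMOGENEOUS),
    "TgWAP-T121":               (6, [("Erbb2-like", 3), ("Class3", 2),
                                     ("Claudin-low", 1)], 0, SEMI_HOMOGENEOUS),
    "TgWAP-T121-Trp53":         (1, [("C3Tag", 1)], 0, ""),
    "TgWAP-Tag":                (4, [("C3Tag", 4)], 0, HOMOGENEOUS),
    "Trp53-null":               (58, [("p53null-Luminal", 27), ("p53null-Basal", 15)], 5,
                                 HETEROGENEOUS),
    "Trp53-het-irradiated":     (8, [("p53null-Basal", 4), ("Claudin-low", 2)], 2,
                                 HETEROGENEOUS),
}

#: models whose printed label contradicts the share rule applied to all
#: tumors; both reconcile when only class-assigned tumors are counted
KNOWN_EXCEPTIONS = ("TgMMTV-PyMT", "TgMMTV-Wnt1-iFgfr")


def possible_categories(n: int, listed: list[tuple[str, int]],
                        n_other_classes: int | None,
                        share: float = 0.80) -> set[str]:
    """All 80%-rule categories consistent with a printed membership row.

    Tumors not covered by the listed classes either belong to the stated
    number of unnamed classes (each with >= 1 tumor) or are unassigned.
    When the count of unnamed classes is not stated, every count is tried.
    Enumerates the (small) compositions exactly.
    """
    if n < 2:
        return {INSUFFICIENT_N}
    counts = sorted((c for _, c in listed), reverse=True)
    r = n - sum(counts)
    if r < 0:
        raise ValueError("listed memberships exceed the tumor count")
    k_options = range(0, r + 1) if n_other_classes is None else [n_other_classes]
    cats: set[str] = set()
    for k in k_options:
        if k == 0:
            extras_options: list[tuple[int, ...]] = [()]
        else:
            extras_options = []
            for o in range(k, r + 1):
                for cut in itertools.combinations(range(1, o), k - 1):
                    parts = np.diff((0, *cut, o))
                    extras_options.append(tuple(int(x) for x in parts))
        for extras in extras_options:
            allc = sorted([*counts, *extras], reverse=True)
            top = allc[0] / n
            top2 = sum(allc[:2]) / n
            cats.add(categorize_shares(top, top2, share))
    return cats


def reproduce_homogeneity(share: float = 0.80) -> pd.DataFrame:
    """Apply the 80% rules to every printed membership row.

    Returns one row per model with the printed label, the categories
    consistent with the printed fractions, whether the rule determines the
    label uniquely, and whether it matches.
    """
    rows = []
    for model, (n, listed, k_other, printed) in MODEL_MEMBERSHIP.items():
        possible = possible_categories(n, listed, k_other, share)
        determined = len(possible) == 1
        category = next(iter(possible)) if determined else None
        printed_label = printed if printed else INSUFFICIENT_N
        match = printed_label in possible
        rows.append((model, n, printed_label, sorted(possible), determined,
                     category, match, model in KNOWN_EXCEPTIONS))
    return pd.DataFrame(rows, columns=["model", "n", "printed", "possible",
                                       "determined", "category", "match",
                                       "known_exception"]).set_index("model")


def assigned_only_shares(model: str) -> tuple[float, float]:
    """Top and top-two shares counting only class-assigned tumors, assuming
    no unnamed classes (the reading that reconciles the exceptions)."""
    _, listed, _, _ = MODEL_MEMBERSHIP[model]
    counts = sorted((c for _, c in listed), reverse=True)
    assigned = sum(counts)
    return counts[0] / assigned, sum(counts[:2]) / assigned


# ---------------------------------------------------------------------------
# headline count arithmetic
# ---------------------------------------------------------------------------

#: (numerator, denominator, decimals, printed string)
PRINTED_COUNTS: dict[str, tuple[int, int, int, str]] = {
    "wnt1_ifgfr_early_fraction": (7, 8, 0, "88"),
    "intrinsic_probe_retention": (500, 654, 1, "76.5"),
    "class_coverage": (363, 385, 0, "94"),
}


def percentage(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Report a count ratio as a percentage, half-up at ``decimals``."""
    scale = 10 ** decimals
    return math.floor(numerator / denominator * 100 * scale + 0.5) / scale
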