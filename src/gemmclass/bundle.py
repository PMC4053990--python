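"""Core in-memory containers shared by every pipeline stage.

The unit of exchange is the :class:`ExpressionBundle`: a feature x sample
matrix of log2(Cy5/Cy3) ratios with per-sample annotations and, for raw
two-color array data, the underlying channel intensities. Gene sets and
probe/ortholog maps get their own small containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SPECIES = ("mouse", "human")

#: canonical annotation columns; extra columns are carried through untouched
ANNOTATION_COLUMNS = ("species", "model_or_subtype", "platform", "is_bridge",
                      "latency_weeks")


class BundleError(ValueError):
    """Malformed bundle or incompatible operation input."""


def _check_unique(ids, what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise BundleError(f"duplicate {what} id(s): {', '.join(map(str, dups.index[:5]))}")


@dataclass
class ExpressionBundle:
    """Log2-ratio expression matrix plus sample metadata.

    Parameters
    ----------
    values : DataFrame, features x samples, NaN = missing.
    sample_annotations : DataFrame indexed by sample id with at least the
        columns in :data:`ANNOTATION_COLUMNS` (missing ones are added with
        neutral defaults).
    cy5, cy3 : optional channel-intensity DataFrames of identical shape
        (experimental and reference channel of a two-color array).
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame | None = None
    cy5: pd.DataFrame | None = None
    cy3: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        if self.sample_annotations is None:
            self.sample_annotations = pd.DataFrame(index=self.values.columns)
        ann = self.sample_annotations
        if not ann.index.equals(self.values.columns):
            if set(ann.index) != set(self.values.columns):
                raise BundleError("sample annotations do not match sample ids")
            ann = ann.loc[self.values.columns]
        defaults = {"species": "mouse", "model_or_subtype": "unknown",
                    "platform": "platform0", "is_bridge": False,
                    "latency_weeks": np.nan}
        for col, default in defaults.items():
            if col not in ann.columns:
                ann = ann.assign(**{col: default})
        self.sample_annotations = ann
        for name in ("cy5", "cy3"):
            chan = getattr(self, name)
            if chan is not None and chan.shape != self.values.shape:
                raise BundleError(f"{name} intensity table shape {chan.shape} "
                                  f"!= expression shape {self.values.shape}")

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame) -> "ExpressionBundle":
        """New bundle with replaced matrix; annotations restricted to its samples."""
        ann = self.sample_annotations.loc[values.columns]
        cy5 = self.cy5.loc[values.index, values.columns] if self.cy5 is not None else None
        cy3 = self.cy3.loc[values.index, values.columns] if self.cy3 is not None else None
        return ExpressionBundle(values, ann, cy5, cy3)

    def subset_features(self, feature_ids) -> "ExpressionBundle":
        return self.with_values(self.values.loc[list(feature_ids)])

    def subset_samples(self, sample_ids) -> "ExpressionBundle":
        return self.with_values(self.values[list(sample_ids)])

    def copy(self) -> "ExpressionBundle":
        return ExpressionBundle(
            self.values.copy(), self.sample_annotations.copy(),
            None if self.cy5 is None else self.cy5.copy(),
            None if self.cy3 is None else self.cy3.copy())


@dataclass
class FeatureMap:
    """Probe→gene map and 1:1 mouse↔human ortholog map.

    ``probe_to_gene`` is many-to-one. ``orthologs`` maps mouse gene symbol to
    human gene symbol and must be a bijection on its domain; duplicated
    entries on either side are resolved by keeping the first occurrence
    (resolution is logged by the reader).
    """

    probe_to_gene: dict[str, str] = field(default_factory=dict)
    orthologs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        humans = list(self.orthologs.values())
        if len(set(humans)) != len(humans):
            raise BundleError("ortholog map is not 1:1 after resolution")

    @property
    def human_to_mouse(self) -> dict[str, str]:
        return {h: m for m, h in self.orthologs.items()}

    def ortholog_id(self, mouse_gene: str) -> str | None:
        """Shared ortholog identifier (human symbol) for a mouse gene."""
        return self.orthologs.get(mouse_gene)


@dataclass
class GeneSet:
    """A named gene list. May be empty in memory (e.g. a class with no
    significant signature); empty sets cannot be written to GMT."""

    set_id: str
    description: str
    genes: list[str]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([s.set_id for s in self.sets], "gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def ids(self) -> list[str]:
        return [s.set_id for s in self.sets]
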