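"""Shared data model: sample/metabolite metadata, intensity matrices and
isotopologue sets.

All downstream stages consume these containers; nothing downstream re-parses
files.  Missing values are represented internally as NaN, which is distinct
from 0 (0 is a legitimate measured intensity).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import GROUPS, TISSUES

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula (e.g. ``"C6H8O7"``) into an
    element -> count map.

    Isotopic labelling never appears in formulas; counts are plain atom
    counts of the unlabelled species.
    """
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"malformed elemental formula: {formula!r}")
    counts: dict[str, int] = {}
    for element, num in _FORMULA_TOKEN.findall(formula):
        if not element:
            continue
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    return counts


def carbon_count(formula: str | dict[str, int]) -> int:
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return int(formula.get("C", 0))


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one biological sample (one tissue pool of one animal)."""

    sample_id: str
    tissue: str
    group: str
    replicate: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        if self.tissue == "tumour" and self.group == "Ctrl":
            raise ValueError("tumour tissue cannot carry group Ctrl: "
                             "no tumour exists in Ctrl animals")


@dataclass(frozen=True)
class MetaboliteMeta:
    """Metadata for one annotated metabolite."""

    metabolite_id: str
    name: str
    formula: str
    cls: str = "other"
    one_carbon_id: int | None = None

    def __post_init__(self) -> None:
        parse_formula(self.formula)  # validates
        if self.one_carbon_id is not None and not 1 <= self.one_carbon_id <= 18:
            raise ValueError("one_carbon_id must be in 1..18")

    @property
    def n_carbons(self) -> int:
        return carbon_count(self.formula)


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    dups: set[str] = set()
    for i in ids:
        if i in seen:
            dups.add(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(dups)}")


@dataclass
class IntensityMatrix:
    """Metabolites x samples intensity matrix with aligned metadata.

    ``values`` is a DataFrame indexed by metabolite_id with sample_id
    columns; NaN marks missing cells.  ``scale`` is ``"raw"`` or ``"log"``.
    ``raw_values``, when present, carries the pre-log matrix so that the
    RSD filter can operate on a scale-free statistic.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    metabolites: list[MetaboliteMeta]
    scale: str = "raw"
    raw_values: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log"):
            raise ValueError(f"scale must be 'raw' or 'log', got {self.scale!r}")
        met_ids = [m.metabolite_id for m in self.metabolites]
        smp_ids = [s.sample_id for s in self.samples]
        _check_unique(met_ids, "metabolite_id")
        _check_unique(smp_ids, "sample_id")
        triples = [(s.tissue, s.group, s.replicate) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise ValueError("(tissue, group, replicate) triples must be unique")
        if list(self.values.index) != met_ids or list(self.values.columns) != smp_ids:
            raise ValueError("values index/columns do not match metadata lists")
        if self.scale == "raw":
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=np.inf) < 0:
                raise ValueError("raw-scale intensities must be non-negative")

    # -- convenience -----------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.metabolite_id for m in self.metabolites]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.tissue, s.group, s.replicate) for s in self.samples],
            columns=["sample_id", "tissue", "group", "replicate"],
        ).set_index("sample_id")

    def metabolite_meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (m.metabolite_id, m.name, m.formula, m.cls, m.one_carbon_id)
                for m in self.metabolites
            ],
            columns=["metabolite_id", "name", "formula", "cls", "one_carbon_id"],
        ).set_index("metabolite_id")

    def subset_tissue(self, tissue: str) -> "IntensityMatrix":
        samples = [s for s in self.samples if s.tissue == tissue]
        if not samples:
            raise ValueError(f"no samples for tissue {tissue!r}")
        cols = [s.sample_id for s in samples]
        raw = self.raw_values[cols] if self.raw_values is not None else None
        return IntensityMatrix(self.values[cols], samples, list(self.metabolites),
                               self.scale, raw)

    def subset_metabolites(self, keep_ids: list[str]) -> "IntensityMatrix":
        keep = set(keep_ids)
        mets = [m for m in self.metabolites if m.metabolite_id in keep]
        ids = [m.metabolite_id for m in mets]
        raw = self.raw_values.loc[ids] if self.raw_values is not None else None
        return IntensityMatrix(self.values.loc[ids], list(self.samples), mets,
                               self.scale, raw)

    def groups_present(self) -> list[str]:
        present = {s.group for s in self.samples}
        return [g for g in GROUPS if g in present]

    def samples_in_group(self, group: str, tissue: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.group == group and (tissue is None or s.tissue == tissue)
        ]

    def with_values(self, values: pd.DataFrame, scale: str | None = None
                    ) -> "IntensityMatrix":
        return replace(self, values=values, scale=scale or self.scale)


@dataclass
class IsotopologueSet:
    """Per (metabolite, sample) vectors of raw M+0..M+C intensities."""

    entries: dict[tuple[str, str], np.ndarray]
    metabolites: dict[str, MetaboliteMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (met_id, sample_id), vec in self.entries.items():
            vec = np.asarray(vec, dtype=float)
            self.entries[(met_id, sample_id)] = vec
            meta = self.metabolites.get(met_id)
            if meta is not None and len(vec) != meta.n_carbons + 1:
                raise ValueError(
                    f"isotopologue vector for {met_id} has length {len(vec)}; "
                    f"expected C+1 = {meta.n_carbons + 1}"
                )
            if np.any(vec < 0):
                raise ValueError(f"negative isotopologue intensity for "
                                 f"({met_id}, {sample_id})")

    def metabolite_ids(self) -> list[str]:
        return sorted({m for m, _ in self.entries})

    def sample_ids(self) -> list[str]:
        return sorted({s for _, s in self.entries})
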