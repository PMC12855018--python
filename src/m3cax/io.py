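"""Reading and writing of tabular artifacts.

Wide intensity matrices use metabolite rows and sample columns; missing
values are encoded on disk as empty cells or ``NA``.  Sample columns are
ordered by (tissue, group, replicate) on write so that re-runs produce
byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import GROUPS, TISSUES
from .datatypes import IntensityMatrix, IsotopologueSet, MetaboliteMeta, SampleMeta

_NA_TOKENS = ["", "NA", "NaN", "nan"]


def _read_table(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, na_values=_NA_TOKENS,
                       keep_default_na=False, **kw)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = _read_table(path)
    required = {"sample_id", "tissue", "group", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample metadata must have columns {sorted(required)}")
    return [
        SampleMeta(str(r.sample_id), str(r.tissue), str(r.group), int(r.replicate))
        for r in df.itertuples()
    ]


def read_metabolite_meta(path: str | Path) -> list[MetaboliteMeta]:
    df = _read_table(path)
    required = {"metabolite_id", "name", "formula"}
    if not required.issubset(df.columns):
        raise ValueError(f"metabolite metadata must have columns {sorted(required)}")
    out = []
    for r in df.itertuples():
        oc = getattr(r, "one_carbon_id", None)
        oc = None if oc is None or (isinstance(oc, float) and np.isnan(oc)) else int(oc)
        out.append(
            MetaboliteMeta(
                str(r.metabolite_id), str(r.name), str(r.formula),
                str(getattr(r, "cls", "other")), oc,
            )
        )
    return out


def read_intensity_table(
    path: str | Path,
    sample_meta_path: str | Path,
    metabolite_meta_path: str | Path,
    scale: str = "raw",
) -> IntensityMatrix:
    """Read a wide metabolite x sample CSV/TSV together with its metadata.

    Raises on duplicate ids and on sample columns absent from the metadata,
    naming the offending identifiers.
    """
    samples = read_sample_meta(sample_meta_path)
    metabolites = read_metabolite_meta(metabolite_meta_path)
    wide = _read_table(path)
    if wide.columns[0] != "metabolite_id":
        raise ValueError("first column of an intensity table must be metabolite_id")
    wide = wide.set_index("metabolite_id")
    if wide.index.duplicated().any():
        dups = sorted(set(wide.index[wide.index.duplicated()]))
        raise ValueError(f"duplicate metabolite_id in {path}: {dups}")

    meta_by_id = {m.metabolite_id: m for m in metabolites}
    unknown_rows = [i for i in wide.index if i not in meta_by_id]
    if unknown_rows:
        raise ValueError(f"metabolite rows absent from metadata: {unknown_rows}")
    sample_by_id = {s.sample_id: s for s in samples}
    missing_cols = [c for c in wide.columns if c not in sample_by_id]
    if missing_cols:
        raise ValueError(f"sample columns absent from metadata: {missing_cols}")

    used_samples = [sample_by_id[c] for c in wide.columns]
    used_metabolites = [meta_by_id[i] for i in wide.index]
    return IntensityMatrix(wide.astype(float), used_samples, used_metabolites,
                           scale=scale)


def _sample_sort_key(s: SampleMeta) -> tuple:
    return (TISSUES.index(s.tissue), GROUPS.index(s.group), s.replicate)


def write_intensity_table(
    matrix: IntensityMatrix, path: str | Path,
    sample_meta_path: str | Path | None = None,
    metabolite_meta_path: str | Path | None = None,
) -> None:
    """Write the wide matrix (and optionally its metadata tables)."""
    samples = sorted(matrix.samples, key=_sample_sort_key)
    cols = [s.sample_id for s in samples]
    out = matrix.values[cols]
    out.to_csv(path, index_label="metabolite_id", na_rep="NA")
    if sample_meta_path is not None:
        matrix.sample_meta_frame().loc[cols].to_csv(sample_meta_path)
    if metabolite_meta_path is not None:
        matrix.metabolite_meta_frame().to_csv(metabolite_meta_path, na_rep="")


def read_isotopologue_table(
    path: str | Path, metabolite_meta_path: str | Path
) -> IsotopologueSet:
    """Read a long-format isotopologue intensity table.

    Columns: metabolite_id, sample_id, mass_shift, intensity.  Absent mass
    shifts are densified to 0; a mass shift beyond the metabolite's carbon
    count is a hard error.
    """
    metabolites = {m.metabolite_id: m for m in read_metabolite_meta(metabolite_meta_path)}
    df = _read_table(path)
    required = {"metabolite_id", "sample_id", "mass_shift", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"isotopologue table must have columns {sorted(required)}")
    entries: dict[tuple[str, str], np.ndarray] = {}
    for (met_id, sample_id), grp in df.groupby(["metabolite_id", "sample_id"],
                                               sort=True):
        met_id, sample_id = str(met_id), str(sample_id)
        if met_id not in metabolites:
            raise ValueError(f"metabolite {met_id!r} absent from metadata")
        n_c = metabolites[met_id].n_carbons
        vec = np.zeros(n_c + 1)
        for _, row in grp.iterrows():
            k = int(row["mass_shift"])
            if not 0 <= k <= n_c:
                raise ValueError(
                    f"mass shift M+{k} exceeds carbon count {n_c} "
                    f"for metabolite {met_id}"
                )
            vec[k] = float(row["intensity"])
        entries[(met_id, sample_id)] = vec
    return IsotopologueSet(entries, metabolites)


def write_isotopologue_table(iso: IsotopologueSet, path: str | Path) -> None:
    rows = []
    for (met_id, sample_id) in sorted(iso.entries):
        for k, v in enumerate(iso.entries[(met_id, sample_id)]):
            rows.append((met_id, sample_id, k, v))
    pd.DataFrame(rows, columns=["metabolite_id", "sample_id", "mass_shift",
                                "intensity"]).to_csv(path, index=False)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path
                  ) -> pd.DataFrame:
    """Write one CSV per named table; return a manifest of files and row counts.

    Column order is taken from each table as given (deterministic); table
    names are written in sorted order so that the manifest is stable.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc
    manifest_rows = []
    for name in sorted(tables):
        fname = f"{name}.csv"
        tables[name].to_csv(out_dir / fname, index=False, na_rep="NA")
        manifest_rows.append((fname, len(tables[name])))
    manifest = pd.DataFrame(manifest_rows, columns=["file", "n_rows"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
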