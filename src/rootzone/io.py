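"""Readers, writers and provenance for the tabular interfaces.

Profiles travel as long-format CSV/TSV with columns root_id, genotype,
day, tissue, cell_index, cell_length_um, is_first_hair (0/1); cell indices
are 1-based from the first cell distal to the QC.  Every writer drops a
provenance JSON (config hash, seed, package version) beside its output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .fitting import MeasuredProfile

PROFILE_COLUMNS = ["root_id", "genotype", "day", "tissue", "cell_index",
                   "cell_length_um", "is_first_hair"]
_REQUIRED = ["root_id", "cell_index", "cell_length_um"]


class ProfileFormatError(ValueError):
    pass


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ProfileFormatError(f"{path}: empty file")
    return df


def profiles_from_frame(df: pd.DataFrame) -> list[MeasuredProfile]:
    """Validate and group a long-format profile table (see module docstring)."""
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ProfileFormatError(f"missing required columns: {missing}")
    bad = df.index[df["cell_length_um"] <= 0].tolist()
    if bad:
        raise ProfileFormatError(
            f"non-positive cell length at rows {[i + 2 for i in bad[:10]]}"
            " (1-based, incl. header)")
    dup = df.duplicated(subset=["root_id", "cell_index"])
    if dup.any():
        rows = df.index[dup].tolist()
        raise ProfileFormatError(
            f"duplicate (root_id, cell_index) at rows {[i + 2 for i in rows[:10]]}")
    profiles = []
    for rid, grp in df.groupby("root_id", sort=False):
        if "tissue" in grp.columns and grp["tissue"].nunique() > 1:
            raise ProfileFormatError(f"root {rid}: mixed tissues in one root_id")
        grp = grp.sort_values("cell_index")
        hair = grp.index[grp.get("is_first_hair", pd.Series(0, index=grp.index))
                         .astype(int) == 1]
        n = len(grp)
        first_hair = (int(grp.loc[hair[0], "cell_index"]) if len(hair)
                      else n + 1)
        profiles.append(MeasuredProfile(
            root_id=str(rid),
            lengths=grp["cell_length_um"].to_numpy(float),
            first_hair_index=first_hair,
            genotype=str(grp["genotype"].iloc[0]) if "genotype" in grp else "unknown",
            day=int(grp["day"].iloc[0]) if "day" in grp else None,
            tissue=str(grp["tissue"].iloc[0]) if "tissue" in grp else "epidermis",
        ))
    return profiles


def read_profiles(path: str | Path) -> list[MeasuredProfile]:
    """Read and validate a profiles CSV/TSV into MeasuredProfile objects."""
    return profiles_from_frame(_read_table(path))


def read_root_lengths(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [c for c in ("root_id", "day", "root_length_mm")
               if c not in df.columns]
    if missing:
        raise ProfileFormatError(f"root-length table missing columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_traits(path: str | Path) -> pd.DataFrame:
    return _read_table(path)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(out_path: str | Path, config: dict,
                     seed: int | None) -> Path:
    """Drop a <output>.provenance.json next to an output file."""
    from . import __version__
    out_path = Path(out_path)
    prov = {"output": out_path.name, "config": config, "seed": seed,
            "config_hash": config_hash(config), "version": __version__}
    prov_path = out_path.with_suffix(out_path.suffix + ".provenance.json")
    prov_path.parent.mkdir(parents=True, exist_ok=True)
    prov_path.write_text(json.dumps(prov, indent=2, default=str) + "\n")
    return prov_path
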