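"""Curated cross-species mAb PK dataset: containers, readers, and unit helpers.

The packaged dataset holds weight-normalized clearance (CL, mL/h/kg) and
subcutaneous bioavailability (SC%F, %) for 25 therapeutic monoclonal
antibodies across rat, cynomolgus monkey, and human.  Missing cells are
genuinely absent values, never zero.  All downstream analyses (correlation
tables, allometric models, scaling summaries) subset this dataset through
:func:`complete_cases`, which is order-stable so that resampling is
reproducible.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BODY_WEIGHTS_KG",
    "SpeciesPKObservation",
    "AntibodyRecord",
    "CrossSpeciesDataset",
    "load_dataset",
    "load_wide_dataset",
    "complete_cases",
    "to_absolute_cl",
    "from_absolute_cl",
    "summarize_measure",
]

SPECIES = ("rat", "monkey", "human")

#: Typical total body weights (kg) used to convert CL between
#: weight-normalized (mL/h/kg) and absolute (L/day) units.
BODY_WEIGHTS_KG = {"rat": 0.3, "monkey": 3.0, "human": 70.0}

PROVENANCE_LEVELS = ("de_novo_rat_study", "regulatory_label", "internal")

Measure = Literal["CL", "SCF"]

_PACKAGED_CSV = "mab_pk_crossspecies.csv"


@dataclass(frozen=True)
class SpeciesPKObservation:
    """One species' PK observation for one antibody.

    SC%F values above 100% are legal and retained as experimentally
    determined; a censor-at-100 sensitivity toggle lives in the correlation
    module, not here.
    """

    species: str
    cl_per_kg: float | None = None  # mL/h/kg
    sc_f_pct: float | None = None  # percent
    provenance: str = "internal"

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.cl_per_kg is not None and not self.cl_per_kg > 0:
            raise ValueError(f"cl_per_kg must be positive, got {self.cl_per_kg}")
        if self.sc_f_pct is not None and not self.sc_f_pct > 0:
            raise ValueError(f"sc_f_pct must be positive, got {self.sc_f_pct}")
        if self.provenance not in PROVENANCE_LEVELS:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def body_weight(self) -> float:
        return BODY_WEIGHTS_KG[self.species]

    def value(self, measure: Measure) -> float | None:
        return self.cl_per_kg if measure == "CL" else self.sc_f_pct


@dataclass(frozen=True)
class AntibodyRecord:
    """All species observations for one antibody (at most one per species)."""

    name: str
    observations: dict[str, SpeciesPKObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, obs in self.observations.items():
            if obs.species != sp:
                raise ValueError(f"{self.name}: key {sp!r} != observation species {obs.species!r}")

    def value(self, species: str, measure: Measure) -> float | None:
        obs = self.observations.get(species)
        return None if obs is None else obs.value(measure)


class CrossSpeciesDataset:
    """Ordered collection of :class:`AntibodyRecord`.

    Record order is the curated table's row order and every subsetting
    operation preserves it, so bootstrap indexing is reproducible.
    Units are fixed: CL in mL/h/kg, SC%F in percent.
    """

    cl_unit = "mL/h/kg"
    f_unit = "%"

    def __init__(self, records: Sequence[AntibodyRecord]):
        names = [r.name for r in records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate antibody names: {dupes}")
        self.records: list[AntibodyRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> AntibodyRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def subset(self, names: Iterable[str]) -> "CrossSpeciesDataset":
        wanted = list(names)
        by_name = {r.name: r for r in self.records}
        return CrossSpeciesDataset([by_name[n] for n in wanted])

    def resample(self, indices: Sequence[int], rename: bool = True) -> "CrossSpeciesDataset":
        """Cluster resample: whole antibodies (all their species observations).

        Duplicated records are renamed (``name#k``) to keep names unique.
        """
        seen: dict[str, int] = {}
        out = []
        for i in indices:
            rec = self.records[int(i)]
            k = seen.get(rec.name, 0)
            seen[rec.name] = k + 1
            name = rec.name if (k == 0 or not rename) else f"{rec.name}#{k}"
            out.append(AntibodyRecord(name=name, observations=rec.observations))
        return CrossSpeciesDataset(out)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame mirroring the curated table's layout (NaN = missing)."""
        rows = []
        for rec in self.records:
            row: dict[str, object] = {"antibody": rec.name}
            for sp in SPECIES:
                row[f"{sp}_cl_ml_h_kg"] = rec.value(sp, "CL")
                row[f"{sp}_scf_pct"] = rec.value(sp, "SCF")
            rows.append(row)
        return pd.DataFrame(rows).astype({"antibody": str})

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for sp in SPECIES:
                obs = rec.observations.get(sp)
                if obs is None:
                    continue
                rows.append(
                    dict(
                        antibody=rec.name,
                        species=sp,
                        cl_ml_h_kg=obs.cl_per_kg,
                        scf_pct=obs.sc_f_pct,
                        provenance=obs.provenance,
                    )
                )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def _parse_cell(value, column: str) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "-", "NA", "nan"):
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"non-numeric value {value!r} in column {column!r}") from exc


def _records_from_long(df: pd.DataFrame) -> list[AntibodyRecord]:
    required = {"antibody", "species", "cl_ml_h_kg", "scf_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long-format CSV missing columns: {sorted(missing)}")
    records: dict[str, dict[str, SpeciesPKObservation]] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        name = str(row["antibody"])
        sp = str(row["species"]).strip().lower()
        if sp not in SPECIES:
            raise ValueError(f"unknown species label {row['species']!r} for {name!r}")
        if name not in records:
            records[name] = {}
            order.append(name)
        if sp in records[name]:
            raise ValueError(f"duplicate observation for ({name!r}, {sp!r})")
        cl = _parse_cell(row["cl_ml_h_kg"], "cl_ml_h_kg")
        f = _parse_cell(row["scf_pct"], "scf_pct")
        if cl is None and f is None:
            continue
        prov = str(row["provenance"]) if "provenance" in df.columns and not pd.isna(row.get("provenance")) else "internal"
        records[name][sp] = SpeciesPKObservation(species=sp, cl_per_kg=cl, sc_f_pct=f, provenance=prov)
    return [AntibodyRecord(name=n, observations=records[n]) for n in order]


def load_dataset(source: str = "packaged") -> CrossSpeciesDataset:
    """Load a cross-species PK dataset from a long-format CSV.

    ``source="packaged"`` loads the curated 25-antibody table shipped with
    the package.  The long schema is one row per (antibody, species):
    ``antibody,species,cl_ml_h_kg,scf_pct,provenance``; empty cells are
    missing values.
    """
    if source == "packaged":
        ref = importlib.resources.files("mabscale.data").joinpath(_PACKAGED_CSV)
        with ref.open("rb") as fh:
            df = pd.read_csv(fh, dtype=str)
    else:
        df = pd.read_csv(source, dtype=str)
    return CrossSpeciesDataset(_records_from_long(df))


def load_wide_dataset(path) -> CrossSpeciesDataset:
    """Read a wide single-row-per-antibody CSV (one column pair per species).

    Expected columns: ``antibody`` plus ``{species}_cl_ml_h_kg`` and/or
    ``{species}_scf_pct`` for any subset of rat/monkey/human.
    """
    df = pd.read_csv(path, dtype=str)
    if "antibody" not in df.columns:
        raise ValueError("wide-format CSV must have an 'antibody' column")
    records = []
    for _, row in df.iterrows():
        obs: dict[str, SpeciesPKObservation] = {}
        for sp in SPECIES:
            cl = _parse_cell(row.get(f"{sp}_cl_ml_h_kg"), f"{sp}_cl_ml_h_kg")
            f = _parse_cell(row.get(f"{sp}_scf_pct"), f"{sp}_scf_pct")
            if cl is not None or f is not None:
                obs[sp] = SpeciesPKObservation(species=sp, cl_per_kg=cl, sc_f_pct=f)
        records.append(AntibodyRecord(name=str(row["antibody"]), observations=obs))
    return CrossSpeciesDataset(records)


def complete_cases(
    ds: CrossSpeciesDataset, species_a: str, species_b: str, measure: Measure = "CL"
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Paired values for antibodies with the measure present in both species.

    Returns ``(names, values_a, values_b)`` in dataset order.
    """
    if measure not in ("CL", "SCF"):
        raise ValueError(f"unknown measure {measure!r} (expected 'CL' or 'SCF')")
    for sp in (species_a, species_b):
        if sp not in SPECIES:
            raise ValueError(f"unknown species {sp!r}")
    if species_a == species_b:
        raise ValueError("species_a and species_b must differ")
    names, xs, ys = [], [], []
    for rec in ds:
        va = rec.value(species_a, measure)
        vb = rec.value(species_b, measure)
        if va is not None and vb is not None:
            names.append(rec.name)
            xs.append(va)
            ys.append(vb)
    return names, np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def to_absolute_cl(cl_per_kg, body_weight_kg):
    """Convert weight-normalized CL (mL/h/kg) to absolute CL (L/day).

    L/day = mL/h/kg x kg x 24 h/day / 1000 mL/L.
    """
    cl_per_kg = np.asarray(cl_per_kg, dtype=float)
    bw = np.asarray(body_weight_kg, dtype=float)
    if np.any(cl_per_kg < 0):
        raise ValueError("cl_per_kg must be non-negative")
    if np.any(bw <= 0):
        raise ValueError("body_weight_kg must be positive")
    out = cl_per_kg * bw * 24.0 / 1000.0
    return float(out) if out.ndim == 0 else out


def from_absolute_cl(cl_l_day, body_weight_kg):
    """Inverse of :func:`to_absolute_cl` (exact round-trip)."""
    cl = np.asarray(cl_l_day, dtype=float)
    bw = np.asarray(body_weight_kg, dtype=float)
    if np.any(cl < 0):
        raise ValueError("cl_l_day must be non-negative")
    if np.any(bw <= 0):
        raise ValueError("body_weight_kg must be positive")
    out = cl * 1000.0 / (24.0 * bw)
    return float(out) if out.ndim == 0 else out


def summarize_measure(ds: CrossSpeciesDataset, species: str, measure: Measure) -> dict:
    """Arithmetic mean / min / max / n over non-missing values."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    vals = [v for rec in ds if (v := rec.value(species, measure)) is not None]
    if not vals:
        raise ValueError(f"no non-missing {measure} values for {species}")
    arr = np.asarray(vals, dtype=float)
    return {"mean": float(arr.mean()), "min": float(arr.min()), "max": float(arr.max()), "n": int(arr.size)}
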