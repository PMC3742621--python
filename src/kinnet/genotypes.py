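"""Codominant multilocus genotype tables and file I/O.

A :class:`GenotypeTable` holds diploid microsatellite genotypes: for every
(individual, locus) cell either an unordered pair of positive integer allele
codes (fragment sizes) or a fully missing call.  Two on-disk dialects are
supported: classic GenePop (2- or 3-digit allele encoding, ``00``/``000`` =
missing) and a wide CSV with two columns per locus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeTable",
    "IndividualMeta",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "read_metadata",
    "write_metadata",
]

#: Sentinel allele code for a missing call (both slots carry it).
MISSING = -1

SEXES = {"M", "F", "unknown"}
STAGES = {"juvenile", "immature", "mature"}


class GenotypeParseError(ValueError):
    """Raised when a genotype file does not parse under its dialect."""


class GenotypeTable:
    """Individuals x loci table of unordered diploid allele pairs.

    Parameters
    ----------
    individuals
        Unique individual identifiers, order preserved.
    loci
        Unique locus names, order preserved.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele codes
        are positive integers, missing cells are ``(MISSING, MISSING)``.
        Pairs are canonicalised so the smaller code comes first.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        individuals = [str(i) for i in individuals]
        loci = [str(l) for l in loci]
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual IDs")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus names")
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(individuals), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} != {(len(individuals), len(loci), 2)}"
            )
        half = (calls == MISSING).sum(axis=2)
        if np.any(half == 1):
            i, l = np.argwhere(half == 1)[0]
            raise ValueError(
                f"half-missing call for individual {individuals[i]!r} at locus "
                f"{loci[l]!r}: a cell must be fully typed or fully missing"
            )
        typed = half == 0
        if np.any(calls[typed] <= 0):
            raise ValueError("allele codes must be positive integers")
        calls = np.sort(calls, axis=2)  # canonical order, smaller code first
        self.individuals = individuals
        self.loci = loci
        self.calls = calls
        self._ind_index = {ind: i for i, ind in enumerate(individuals)}
        self._locus_index = {loc: i for i, loc in enumerate(loci)}

    # ------------------------------------------------------------------ basics
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of fully typed cells."""
        return self.calls[:, :, 0] != MISSING

    def get(self, individual: str, locus: str):
        """Return the unordered allele pair as a tuple, or ``None`` if missing."""
        i = self._ind_index[individual]
        l = self._locus_index[locus]
        a, b = self.calls[i, l]
        return None if a == MISSING else (int(a), int(b))

    def locus_calls(self, locus: str) -> np.ndarray:
        """All calls at one locus, shape (n_individuals, 2), missing rows included."""
        return self.calls[:, self._locus_index[locus], :]

    def subset_individuals(self, ids: Iterable[str]) -> "GenotypeTable":
        ids = list(ids)
        idx = [self._ind_index[i] for i in ids]
        return GenotypeTable(ids, self.loci, self.calls[idx].copy())

    def subset_loci(self, loci: Iterable[str]) -> "GenotypeTable":
        loci = list(loci)
        idx = [self._locus_index[l] for l in loci]
        return GenotypeTable(self.individuals, loci, self.calls[:, idx].copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeTable({self.n_individuals} individuals x "
            f"{self.n_loci} loci)"
        )


@dataclass
class IndividualMeta:
    """Per-individual metadata: sex, size, stage, residency group, site, cohort.

    Stage categories follow total-length thresholds (juvenile < 100 cm,
    immature 100-199 cm, mature >= 200 cm); when both stage and length are
    given they must agree.
    """

    id: str
    sex: str = "unknown"
    total_length_cm: float | None = None
    stage: str | None = None
    group: str | None = None
    site: str | None = None
    cohort_year: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {sorted(SEXES)}, got {self.sex!r}")
        if self.stage is not None and self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage is not None and self.total_length_cm is not None:
            expected = stage_from_length(self.total_length_cm)
            if expected != self.stage:
                raise ValueError(
                    f"stage {self.stage!r} inconsistent with total length "
                    f"{self.total_length_cm} cm (implies {expected!r})"
                )


def stage_from_length(total_length_cm: float) -> str:
    """Maturity stage from total length (cm): <100 juvenile, <200 immature, else mature."""
    if total_length_cm < 100:
        return "juvenile"
    if total_length_cm < 200:
        return "immature"
    return "mature"


# --------------------------------------------------------------------- GenePop

_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def _parse_genepop(path: Path) -> GenotypeTable:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenotypeParseError(f"{path}: too short for a GenePop file")
    # line 1: title (ignored); then locus names until the first "Pop"
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i].strip()):
        chunk = lines[i].strip()
        if chunk:
            # locus names may be one per line or comma-separated on one line
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if i == len(lines):
        raise GenotypeParseError(f"{path}: no 'Pop' line found")
    individuals: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for lineno in range(i, len(lines)):
        raw = lines[lineno].strip()
        if not raw:
            continue
        if _POP_RE.match(raw):
            continue
        if "," not in raw:
            raise GenotypeParseError(
                f"{path}:{lineno + 1}: expected 'ID , genotypes', no comma found"
            )
        ind_id, _, geno_part = raw.partition(",")
        ind_id = ind_id.strip()
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise GenotypeParseError(
                f"{path}:{lineno + 1}: {len(fields)} genotype fields for "
                f"{len(loci)} loci"
            )
        row = []
        for field, locus in zip(fields, loci):
            if len(field) == 4:
                digits = 2
            elif len(field) == 6:
                digits = 3
            else:
                raise GenotypeParseError(
                    f"{path}:{lineno + 1}: genotype {field!r} at locus {locus} "
                    "is neither 4 (2-digit) nor 6 (3-digit) characters"
                )
            if not field.isdigit():
                raise GenotypeParseError(
                    f"{path}:{lineno + 1}: non-numeric genotype {field!r}"
                )
            a, b = int(field[:digits]), int(field[digits:])
            if (a == 0) != (b == 0):
                raise GenotypeParseError(
                    f"{path}:{lineno + 1}: half-missing genotype {field!r} "
                    f"at locus {locus}"
                )
            row.append((MISSING, MISSING) if a == 0 else (a, b))
        if ind_id in individuals:
            raise GenotypeParseError(
                f"{path}:{lineno + 1}: duplicate individual ID {ind_id!r}"
            )
        individuals.append(ind_id)
        rows.append(row)
    calls = np.array(rows, dtype=np.int64).reshape(len(individuals), len(loci), 2)
    return GenotypeTable(individuals, loci, calls)


def _write_genepop(table: GenotypeTable, path: Path, title: str = "kinnet export") -> None:
    digits = 3 if int(table.calls.max(initial=0)) > 99 else 2
    if int(table.calls.max(initial=0)) > 999:
        raise ValueError("GenePop encoding supports allele codes up to 999")
    out = [title]
    out.extend(table.loci)
    out.append("Pop")
    for i, ind in enumerate(table.individuals):
        fields = []
        for l in range(table.n_loci):
            a, b = table.calls[i, l]
            if a == MISSING:
                a = b = 0
            fields.append(f"{a:0{digits}d}{b:0{digits}d}")
        out.append(f"{ind} ,  " + " ".join(fields))
    path.write_text("\n".join(out) + "\n")


# ------------------------------------------------------------------------- CSV


def _parse_csv(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "id":
        raise GenotypeParseError(f"{path}: first CSV column must be 'id'")
    loci: list[str] = []
    for col in df.columns[1:]:
        if not (col.endswith(".1") or col.endswith(".2")):
            raise GenotypeParseError(
                f"{path}: genotype column {col!r} must be named <locus>.1/<locus>.2"
            )
        name = col[:-2]
        if name not in loci:
            loci.append(name)
    for locus in loci:
        for suffix in (".1", ".2"):
            if locus + suffix not in df.columns:
                raise GenotypeParseError(f"{path}: missing column {locus + suffix!r}")
    individuals = df["id"].tolist()
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise GenotypeParseError(f"{path}: duplicate individual ID {dup!r}")
    calls = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int64)
    for l, locus in enumerate(loci):
        a = df[locus + ".1"].to_numpy()
        b = df[locus + ".2"].to_numpy()
        a_missing = pd.isna(a)
        b_missing = pd.isna(b)
        if np.any(a_missing != b_missing):
            bad = int(np.argwhere(a_missing != b_missing)[0][0])
            raise GenotypeParseError(
                f"{path}: half-missing call for {individuals[bad]!r} at {locus}"
            )
        typed = ~a_missing
        calls[typed, l, 0] = np.asarray(a[typed], dtype=float).astype(np.int64)
        calls[typed, l, 1] = np.asarray(b[typed], dtype=float).astype(np.int64)
    return GenotypeTable(individuals, loci, calls)


def _write_csv(table: GenotypeTable, path: Path) -> None:
    data: dict[str, list] = {"id": table.individuals}
    for l, locus in enumerate(table.loci):
        col_a, col_b = [], []
        for i in range(table.n_individuals):
            a, b = table.calls[i, l]
            col_a.append("" if a == MISSING else int(a))
            col_b.append("" if b == MISSING else int(b))
        data[locus + ".1"] = col_a
        data[locus + ".2"] = col_b
    pd.DataFrame(data).to_csv(path, index=False)


# --------------------------------------------------------------------- fronts


def read_genotypes(path, format: str = "genepop") -> GenotypeTable:
    """Read a genotype table from ``path`` in the named dialect.

    GenePop 2- and 3-digit encodings are both accepted; ``00``/``000`` decodes
    as missing.  The CSV dialect has an ``id`` column plus two columns per
    locus named ``<locus>.1``/``<locus>.2`` with empty cells for missing data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genepop":
        return _parse_genepop(path)
    if format == "csv":
        return _parse_csv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(table: GenotypeTable, path, format: str = "genepop") -> None:
    """Write ``table`` to ``path``; inverse of :func:`read_genotypes`."""
    path = Path(path)
    if format == "genepop":
        _write_genepop(table, path)
    elif format == "csv":
        _write_csv(table, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_metadata(path) -> dict[str, IndividualMeta]:
    """Read an individual-metadata CSV keyed by individual ID.

    Expected columns: id, sex, total_length_cm, stage, group, site,
    cohort_year; empty cells mean unknown.
    """
    df = pd.read_csv(path, dtype={"id": str})
    out: dict[str, IndividualMeta] = {}
    for _, row in df.iterrows():
        def _get(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) or v == "" else v

        meta = IndividualMeta(
            id=str(row["id"]),
            sex=_get("sex") or "unknown",
            total_length_cm=(
                float(row["total_length_cm"])
                if _get("total_length_cm") is not None
                else None
            ),
            stage=_get("stage"),
            group=_get("group"),
            site=_get("site"),
            cohort_year=(
                int(row["cohort_year"]) if _get("cohort_year") is not None else None
            ),
        )
        out[meta.id] = meta
    return out


def write_metadata(meta: Mapping[str, IndividualMeta], path) -> None:
    rows = []
    for m in meta.values():
        rows.append(
            {
                "id": m.id,
                "sex": m.sex,
                "total_length_cm": m.total_length_cm,
                "stage": m.stage,
                "group": m.group,
                "site": m.site,
                "cohort_year": m.cohort_year,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
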