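"""Readers and writers for genotype and phenotype tables.

Genotypes are codominant microsatellite calls: each individual carries an
unordered pair of integer allele codes per locus, or the whole locus is
missing.  Missing data is always per-locus — a half-called genotype is a
format error, never silently coerced.

In-memory convention: allele codes are positive integers <= 999 and the
missing marker is 0.  Offspring matrices are ``numpy`` integer arrays of
shape ``(n_offspring, n_loci, 2)``; a missing locus is ``(0, 0)``.

Two genotype serialisations are supported:

* GenePop (title line, locus list, ``pop`` blocks, 2- or 3-digit codes,
  ``00``/``000`` missing), the lingua franca of population-genetics tools;
* a family-structured TSV dialect (columns ``population``, ``family``,
  ``individual``, ``role``, then one column per locus holding ``a1/a2`` with
  ``.`` for missing) that keeps the mother/offspring structure explicit.

Phenotype tables (per-flower herkogamy, hand-pollination fitness records,
per-family mating-system parameters) are plain TSV read into pandas frames
with validation.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = 0

__all__ = [
    "MISSING",
    "FormatError",
    "ProgenyArray",
    "GenotypeCollection",
    "read_genepop",
    "write_genepop",
    "read_progeny_table",
    "write_progeny_table",
    "arrays_to_collection",
    "collection_to_arrays",
    "read_herkogamy_table",
    "write_herkogamy_table",
    "read_fitness_table",
    "write_fitness_table",
    "read_family_parameters",
]


class FormatError(ValueError):
    """Malformed input file; carries a line/row locator in the message."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ProgenyArray:
    """One maternal family: optional maternal genotype plus its progeny array.

    Parameters
    ----------
    family_id, population_id : str
        Identifiers; family ids must be unique within a population.
    locus_names : list of str
        Shared locus order for mother and offspring.
    offspring : ndarray of int, shape (n_offspring, n_loci, 2)
        Allele codes, ``0`` marking a missing locus (both entries zero).
    maternal : ndarray of int, shape (n_loci, 2), optional
        The maternal multilocus genotype when directly genotyped; ``None``
        when it must be inferred from the progeny.
    """

    family_id: str
    population_id: str
    locus_names: list[str]
    offspring: np.ndarray
    maternal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.offspring = np.asarray(self.offspring, dtype=np.int64)
        if self.offspring.ndim != 3 or self.offspring.shape[2] != 2:
            raise ValueError("offspring must have shape (n_offspring, n_loci, 2)")
        if self.offspring.shape[0] < 1:
            raise ValueError("a progeny array needs at least one offspring")
        if self.offspring.shape[1] != len(self.locus_names):
            raise ValueError("offspring locus dimension does not match locus_names")
        if self.maternal is not None:
            self.maternal = np.asarray(self.maternal, dtype=np.int64)
            if self.maternal.shape != (len(self.locus_names), 2):
                raise ValueError("maternal genotype shape does not match locus_names")
        _check_pairwise_missing(self.offspring, self.family_id)
        if self.maternal is not None:
            _check_pairwise_missing(self.maternal[None, :, :], self.family_id)

    @property
    def n_offspring(self) -> int:
        return self.offspring.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)


def _check_pairwise_missing(geno: np.ndarray, label: str) -> None:
    half = (geno == MISSING).sum(axis=-1) == 1
    if half.any():
        raise ValueError(
            f"family {label!r}: genotype with exactly one missing allele; "
            "missing data must be per-locus"
        )


@dataclass
class GenotypeCollection:
    """Genotypes grouped into named population ('pop') blocks.

    ``populations`` maps block name -> (individual ids, genotype array of
    shape ``(n_individuals, n_loci, 2)``).  Block order is preserved.
    """

    locus_names: list[str]
    populations: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)
    title: str = "matingkit export"

    def all_genotypes(self) -> np.ndarray:
        """Stack every individual across blocks into one genotype array."""
        parts = [g for _, g in self.populations.values()]
        return np.concatenate(parts, axis=0) if parts else np.empty((0, len(self.locus_names), 2), dtype=np.int64)


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def read_genepop(path: str | Path) -> GenotypeCollection:
    """Parse a GenePop file into a :class:`GenotypeCollection`.

    The allele-code width (2 or 3 digits) is auto-detected from the first
    genotype field and enforced for the whole file.  ``00``/``000`` decodes
    to the missing marker.  Population blocks are named after the id of
    their last individual, GenePop's usual convention, unless that id is
    empty, in which case ``pop_<k>`` is used.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    title = lines[0].strip()

    # locus names: either one per line until the first "pop", or a single
    # comma-separated line
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i].strip()):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise FormatError(f"{path}: no 'pop' separator found")
    if not loci:
        raise FormatError(f"{path}: no locus names before first 'pop'")

    code_width: int | None = None
    blocks: list[tuple[list[str], list[np.ndarray]]] = []
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        stripped = raw.strip()
        if not stripped:
            continue
        if _POP_RE.match(stripped):
            blocks.append(([], []))
            continue
        if "," not in raw:
            raise FormatError(f"{path}:{lineno + 1}: individual line lacks ',' separator")
        ind_id, _, geno_part = raw.partition(",")
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise FormatError(
                f"{path}:{lineno + 1}: expected {len(loci)} genotype fields, got {len(fields)}"
            )
        row = np.zeros((len(loci), 2), dtype=np.int64)
        for j, f in enumerate(fields):
            if not f.isdigit() or len(f) % 2 != 0:
                raise FormatError(f"{path}:{lineno + 1}: malformed genotype field {f!r}")
            w = len(f) // 2
            if w not in (2, 3):
                raise FormatError(f"{path}:{lineno + 1}: unsupported allele code width {w}")
            if code_width is None:
                code_width = w
            elif w != code_width:
                raise FormatError(
                    f"{path}:{lineno + 1}: mixed allele code widths ({w} vs {code_width})"
                )
            a1, a2 = int(f[:w]), int(f[w:])
            if (a1 == 0) != (a2 == 0):
                raise FormatError(
                    f"{path}:{lineno + 1}: half-missing genotype {f!r} at locus {loci[j]}"
                )
            row[j] = (a1, a2)
        blocks[-1][0].append(ind_id.strip())
        blocks[-1][1].append(row)

    coll = GenotypeCollection(locus_names=loci, title=title)
    for k, (ids, rows) in enumerate(blocks):
        if not rows:
            continue
        name = ids[-1] if ids[-1] else f"pop_{k + 1}"
        coll.populations[name] = (ids, np.stack(rows))
    return coll


def write_genepop(coll: GenotypeCollection, path: str | Path, code_width: int = 3) -> None:
    """Write a :class:`GenotypeCollection` as GenePop, LF endings, UTF-8."""
    limit = 10**code_width - 1
    buf = _io.StringIO()
    buf.write(coll.title + "\n")
    for name in coll.locus_names:
        buf.write(name + "\n")
    for _, (ids, geno) in coll.populations.items():
        if geno.max(initial=0) > limit:
            j, a = np.unravel_index(int(np.argmax(geno)), geno.shape)[1:3]
            raise ValueError(
                f"allele code {geno.max()} at locus {coll.locus_names[j]} "
                f"does not fit code width {code_width}"
            )
        buf.write("pop\n")
        for ind_id, row in zip(ids, geno):
            fields = "".join(
                f" {a1:0{code_width}d}{a2:0{code_width}d}" for a1, a2 in row
            )
            buf.write(f"{ind_id} ,{fields}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def arrays_to_collection(arrays: Sequence[ProgenyArray], include_mothers: bool = False) -> GenotypeCollection:
    """Export progeny arrays as a GenePop collection, one pop block per family."""
    if not arrays:
        raise ValueError("no progeny arrays to export")
    loci = arrays[0].locus_names
    coll = GenotypeCollection(locus_names=list(loci))
    for arr in arrays:
        if arr.locus_names != loci:
            raise ValueError(f"family {arr.family_id}: locus list differs across families")
        ids = []
        rows = []
        if include_mothers and arr.maternal is not None:
            ids.append(f"{arr.family_id}_mother")
            rows.append(arr.maternal)
        ids.extend(f"{arr.family_id}_{k + 1}" for k in range(arr.n_offspring))
        rows.extend(arr.offspring)
        # last id names the block; GenePop convention keeps family id visible
        ids[-1] = f"{arr.family_id}"
        coll.populations[arr.family_id] = (ids, np.stack(rows))
    return coll


def collection_to_arrays(coll: GenotypeCollection, population_id: str = "pop") -> list[ProgenyArray]:
    """Interpret each pop block of a GenePop collection as one progeny array."""
    arrays = []
    for name, (_ids, geno) in coll.populations.items():
        arrays.append(
            ProgenyArray(
                family_id=name,
                population_id=population_id,
                locus_names=list(coll.locus_names),
                offspring=geno,
            )
        )
    return arrays


# ---------------------------------------------------------------------------
# family-structured TSV dialect
# ---------------------------------------------------------------------------

_META_COLS = ["population", "family", "individual", "role"]


def _parse_locus_cell(cell: str, path: str, row: int, locus: str) -> tuple[int, int]:
    cell = str(cell).strip()
    if cell in (".", "", "nan", "./."):
        return (MISSING, MISSING)
    parts = cell.split("/")
    if len(parts) != 2:
        raise FormatError(f"{path}: row {row}: locus {locus}: expected 'a1/a2', got {cell!r}")
    try:
        a1, a2 = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise FormatError(f"{path}: row {row}: locus {locus}: non-integer allele in {cell!r}") from exc
    if a1 <= 0 or a2 <= 0:
        raise FormatError(f"{path}: row {row}: locus {locus}: allele codes must be positive")
    return (a1, a2)


def read_progeny_table(path: str | Path) -> list[ProgenyArray]:
    """Read the family-structured TSV dialect into progeny arrays."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in _META_COLS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    locus_names = [c for c in df.columns if c not in _META_COLS]
    if not locus_names:
        raise FormatError(f"{path}: no locus columns")
    arrays: list[ProgenyArray] = []
    for (pop, fam), grp in df.groupby(["population", "family"], sort=False):
        mothers = grp[grp["role"] == "mother"]
        if len(mothers) > 1:
            raise FormatError(f"{path}: family {fam!r}: more than one mother row")
        maternal = None
        if len(mothers) == 1:
            ridx = int(mothers.index[0]) + 2  # header + 1-based
            maternal = np.array(
                [_parse_locus_cell(mothers.iloc[0][lc], str(path), ridx, lc) for lc in locus_names]
            )
        off = grp[grp["role"] == "offspring"]
        if len(off) == 0:
            raise FormatError(f"{path}: family {fam!r}: no offspring rows")
        rows = []
        for idx, rec in off.iterrows():
            ridx = int(idx) + 2
            rows.append([_parse_locus_cell(rec[lc], str(path), ridx, lc) for lc in locus_names])
        arrays.append(
            ProgenyArray(
                family_id=str(fam),
                population_id=str(pop),
                locus_names=locus_names,
                offspring=np.array(rows),
                maternal=maternal,
            )
        )
    return arrays


def write_progeny_table(arrays: Sequence[ProgenyArray], path: str | Path) -> None:
    rows = []
    for arr in arrays:
        if arr.maternal is not None:
            rows.append(_tsv_row(arr, "mother", f"{arr.family_id}_mother", arr.maternal))
        for k in range(arr.n_offspring):
            rows.append(
                _tsv_row(arr, "offspring", f"{arr.family_id}_{k + 1}", arr.offspring[k])
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _tsv_row(arr: ProgenyArray, role: str, ind: str, geno: np.ndarray) -> dict:
    row = {
        "population": arr.population_id,
        "family": arr.family_id,
        "individual": ind,
        "role": role,
    }
    for lc, (a1, a2) in zip(arr.locus_names, geno):
        row[lc] = "." if a1 == MISSING else f"{a1}/{a2}"
    return row


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------


def read_herkogamy_table(path: str | Path) -> pd.DataFrame:
    """Per-flower herkogamy (pistil minus stamen length, mm; signed)."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "plant", "flower", "herkogamy"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if not np.isfinite(df["herkogamy"].to_numpy(dtype=float)).all():
        bad = int(np.flatnonzero(~np.isfinite(df["herkogamy"].to_numpy(dtype=float)))[0]) + 2
        raise FormatError(f"{path}: row {bad}: non-finite herkogamy value")
    return df


def write_herkogamy_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_fitness_table(path: str | Path) -> pd.DataFrame:
    """Hand-pollination fitness records: seed-set in [0,1] and seed mass > 0."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "mother", "treatment", "fruit", "seed_set", "seed_mass"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad_treat = ~df["treatment"].isin(["self", "outcross"])
    if bad_treat.any():
        row = int(np.flatnonzero(bad_treat.to_numpy())[0]) + 2
        raise FormatError(f"{path}: row {row}: treatment must be 'self' or 'outcross'")
    ss = df["seed_set"].to_numpy(dtype=float)
    out = (ss < 0) | (ss > 1) | ~np.isfinite(ss)
    if out.any():
        row = int(np.flatnonzero(out)[0]) + 2
        raise FormatError(f"{path}: row {row}: seed_set outside [0, 1]")
    sm = df["seed_mass"].to_numpy(dtype=float)
    if ((sm <= 0) | ~np.isfinite(sm)).any():
        row = int(np.flatnonzero((sm <= 0) | ~np.isfinite(sm))[0]) + 2
        raise FormatError(f"{path}: row {row}: seed_mass must be positive")
    return df


def write_fitness_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# per-family mating-system parameter tables (published supplementary shape)
# ---------------------------------------------------------------------------

_SYNONYMS = {
    "population": "population",
    "pop": "population",
    "locality": "population",
    "family": "family",
    "fam": "family",
    "lineage": "family",
    "maternal family": "family",
    "herkogamy": "herkogamy",
    "herk": "herkogamy",
    "tm": "tm",
    "t": "tm",
    "outcrossing rate": "tm",
    "multilocus outcrossing rate": "tm",
    "s": "s",
    "selfing rate": "s",
    "r": "r",
    "primary selfing rate": "r",
    "fe": "Fe",
    "f_e": "Fe",
    "f e": "Fe",
    "equilibrium inbreeding": "Fe",
    "inbreeding coefficient at equilibrium": "Fe",
}


def read_family_parameters(path: str | Path) -> pd.DataFrame:
    """Read a per-family mating-system parameter table (TSV or CSV).

    Headers are sniffed case-insensitively and mapped through a synonym
    registry, so published tables using ``t``/``tm``/``outcrossing rate``
    etc. all land on the canonical columns ``population``, ``family``,
    ``herkogamy``, ``tm``, ``s``, ``r``, ``Fe``.  Unrecognised columns are
    preserved untouched.  ``s`` is filled from ``1 - tm`` (and vice versa)
    when only one is present.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    rename = {}
    for col in df.columns:
        key = re.sub(r"[\s_()*]+", " ", str(col)).strip().lower()
        if key in _SYNONYMS:
            rename[col] = _SYNONYMS[key]
    df = df.rename(columns=rename)
    if "tm" in df.columns and "s" not in df.columns:
        df["s"] = 1.0 - df["tm"]
    if "s" in df.columns and "tm" not in df.columns:
        df["tm"] = 1.0 - df["s"]
    return df
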