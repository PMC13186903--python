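"""Genotype, marker-map, panel-label and distance-matrix I/O.

Two text dialects are supported for genotypes:

* ``plink_text`` — a PLINK ``.ped``/``.map`` pair (whitespace separated,
  two allele columns per marker, ``0`` meaning a missing allele);
* ``tsv`` — a simple matrix: header row of marker ids, one row per
  animal, cells coded ``0``/``1``/``2``/``NA``, with a companion
  three-column map file (``marker<TAB>chrom<TAB>pos``).

Genotypes are stored as allele dosages: the number of copies of the B
allele, where B is the lexicographically larger allele observed at the
marker.  Missing calls are kept as a distinct code and never imputed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})

REF_A = "REF_A"
REF_B = "REF_B"
EXPERIMENTAL = "EXPERIMENTAL"
_ROLES = (REF_A, REF_B, EXPERIMENTAL)


class GenotypeFormatError(ValueError):
    """Raised on malformed genotype / map input."""


@dataclasses.dataclass
class SnpMap:
    """Ordered marker map: id, chromosome label and 1-based bp position.

    Chromosome labels are opaque strings; positions must be strictly
    increasing within each chromosome once the map is sorted by
    (chromosome, position).  Optional ``allele_a``/``allele_b`` record
    the dosage orientation chosen when parsing allele-coded input
    (B = ``allele_b`` = lexicographically larger observed allele).
    """

    markers: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    allele_a: np.ndarray | None = None
    allele_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=object)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if not (len(self.markers) == len(self.chroms) == len(self.positions)):
            raise GenotypeFormatError("map columns have unequal lengths")
        if len(set(self.markers)) != len(self.markers):
            raise GenotypeFormatError("duplicated marker id in map")
        if np.any(self.positions <= 0):
            raise GenotypeFormatError("positions must be positive (1-based)")

    def __len__(self) -> int:
        return len(self.markers)

    def is_sorted(self) -> bool:
        """True if (chrom, pos) is non-decreasing with strictly increasing
        positions within each chromosome."""
        for i in range(1, len(self)):
            if self.chroms[i] == self.chroms[i - 1]:
                if self.positions[i] <= self.positions[i - 1]:
                    return False
        order = sort_order(self.chroms, self.positions)
        return bool(np.all(order == np.arange(len(self))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.markers, "chrom": self.chroms, "pos": self.positions}
        )


def sort_order(chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Stable ordering by (chromosome label, position)."""
    return np.lexsort((np.asarray(positions), np.asarray(chroms, dtype=object)))


@dataclasses.dataclass
class GenotypeMatrix:
    """Animals x markers allele-dosage matrix; entries in {0,1,2,MISSING}."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise GenotypeFormatError("genotype values must be 2-D")
        if len(self.ids) != self.values.shape[0]:
            raise GenotypeFormatError("row count does not match animal ids")
        if len(set(self.ids)) != len(self.ids):
            raise GenotypeFormatError("duplicated animal id")
        bad = set(np.unique(self.values)) - _VALID_CODES
        if bad:
            raise GenotypeFormatError(f"invalid dosage codes {sorted(bad)}")

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def row(self, animal_id: str) -> np.ndarray:
        return self.values[self.ids.index(animal_id)]


@dataclasses.dataclass
class PanelLabels:
    """Role of each animal: reference panel A/B or experimental.

    ``breed_a``/``breed_b`` carry the breed names attached to the two
    reference roles (e.g. Pietrain and German Landrace).
    """

    roles: dict[str, str]
    breed_a: str = "A"
    breed_b: str = "B"

    def __post_init__(self) -> None:
        bad = {r for r in self.roles.values() if r not in _ROLES}
        if bad:
            raise GenotypeFormatError(f"unknown roles {sorted(bad)}")

    def ids_with_role(self, role: str) -> list[str]:
        return [a for a, r in self.roles.items() if r == role]

    @property
    def ref_a_ids(self) -> list[str]:
        return self.ids_with_role(REF_A)

    @property
    def ref_b_ids(self) -> list[str]:
        return self.ids_with_role(REF_B)

    @property
    def experimental_ids(self) -> list[str]:
        return self.ids_with_role(EXPERIMENTAL)

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = set(self.roles) - set(gm.ids)
        if missing:
            raise GenotypeFormatError(
                f"labeled animals absent from genotype matrix: {sorted(missing)[:5]}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_genotypes(
    genotype_path: str | Path,
    map_path: str | Path,
    dialect: str = "tsv",
) -> tuple[GenotypeMatrix, SnpMap]:
    """Read a genotype matrix and its marker map.

    Columns of the returned matrix are ordered by (chromosome, position);
    the map is returned in the same order.
    """
    if dialect == "tsv":
        gm, smap = _read_tsv(Path(genotype_path), Path(map_path))
    elif dialect == "plink_text":
        gm, smap = _read_plink_text(Path(genotype_path), Path(map_path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _sort_columns(gm, smap)


def _sort_columns(gm: GenotypeMatrix, smap: SnpMap) -> tuple[GenotypeMatrix, SnpMap]:
    order = sort_order(smap.chroms, smap.positions)
    smap2 = SnpMap(
        smap.markers[order],
        smap.chroms[order],
        smap.positions[order],
        None if smap.allele_a is None else smap.allele_a[order],
        None if smap.allele_b is None else smap.allele_b[order],
    )
    if not smap2.is_sorted():
        raise GenotypeFormatError(
            "duplicate position on a chromosome; positions must be strictly increasing"
        )
    return GenotypeMatrix(gm.ids, gm.values[:, order]), smap2


def _read_map_tsv(path: Path) -> SnpMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str, "pos": np.int64})
    for col in ("marker", "chrom", "pos"):
        if col not in df.columns:
            raise GenotypeFormatError(f"map file {path} lacks column {col!r}")
    return SnpMap(df["marker"].to_numpy(), df["chrom"].to_numpy(), df["pos"].to_numpy())


def _read_tsv(genotype_path: Path, map_path: Path) -> tuple[GenotypeMatrix, SnpMap]:
    smap = _read_map_tsv(map_path)
    with open(genotype_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        markers = header[1:]
        if markers != list(smap.markers):
            # allow any order in the map file; require same set
            if set(markers) != set(smap.markers):
                raise GenotypeFormatError("genotype header and map markers disagree")
            reindex = {m: i for i, m in enumerate(markers)}
            perm = np.array([reindex[m] for m in smap.markers])
        else:
            perm = np.arange(len(markers))
        ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(markers) + 1:
                raise GenotypeFormatError(
                    f"{genotype_path}:{lineno}: expected {len(markers) + 1} fields, "
                    f"got {len(parts)}"
                )
            ids.append(parts[0])
            row = np.empty(len(markers), dtype=np.int8)
            for j, cell in enumerate(parts[1:]):
                if cell in ("NA", "", "."):
                    row[j] = MISSING
                elif cell in ("0", "1", "2"):
                    row[j] = int(cell)
                else:
                    raise GenotypeFormatError(
                        f"{genotype_path}:{lineno}: invalid dosage cell {cell!r}"
                    )
            rows.append(row[perm])
    values = np.vstack(rows) if rows else np.empty((0, len(markers)), dtype=np.int8)
    return GenotypeMatrix(ids, values), smap


def _read_plink_text(ped_path: Path, map_path: Path) -> tuple[GenotypeMatrix, SnpMap]:
    # .map: chrom, marker id, genetic distance (ignored), bp position
    recs = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise GenotypeFormatError(f"{map_path}:{lineno}: expected 4 fields")
            recs.append((parts[1], parts[0], int(parts[3])))
    markers = [r[0] for r in recs]
    if len(set(markers)) != len(markers):
        raise GenotypeFormatError(f"{map_path}: duplicated marker id")
    m = len(markers)

    ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            ids.append(parts[1])
            alleles = parts[6:]
            allele_rows.append(
                [(alleles[2 * j], alleles[2 * j + 1]) for j in range(m)]
            )

    values = np.full((len(ids), m), MISSING, dtype=np.int8)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    for j in range(m):
        observed = sorted(
            {a for row in allele_rows for a in row[j] if a != "0"}
        )
        if len(observed) > 2:
            raise GenotypeFormatError(
                f"marker {markers[j]}: more than two alleles {observed}"
            )
        for a in observed:
            if not a.isalnum():
                raise GenotypeFormatError(
                    f"marker {markers[j]}: unknown allele symbol {a!r}"
                )
        if not observed:
            allele_a[j] = allele_b[j] = None
            continue
        b = observed[-1]  # lexicographically larger allele = B
        allele_a[j] = observed[0]
        allele_b[j] = b
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            values[i, j] = (a1 == b) + (a2 == b)

    smap = SnpMap(
        np.array(markers, dtype=object),
        np.array([r[1] for r in recs], dtype=object),
        np.array([r[2] for r in recs], dtype=np.int64),
        allele_a,
        allele_b,
    )
    return GenotypeMatrix(ids, values), smap


def read_panel_labels(path: str | Path, breed_a: str = "A", breed_b: str = "B") -> PanelLabels:
    """Two-column TSV (animal id, role); optional ``# breed_a=... breed_b=...``
    comment line overrides the breed names."""
    roles: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("breed_a="):
                        breed_a = token.split("=", 1)[1]
                    elif token.startswith("breed_b="):
                        breed_b = token.split("=", 1)[1]
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GenotypeFormatError(f"panel label line not 2 columns: {line!r}")
            roles[parts[0]] = parts[1]
    return PanelLabels(roles, breed_a=breed_a, breed_b=breed_b)


def write_panel_labels(labels: PanelLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# breed_a={labels.breed_a} breed_b={labels.breed_b}\n")
        for animal, role in labels.roles.items():
            fh.write(f"{animal}\t{role}\n")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_genotypes_tsv(
    gm: GenotypeMatrix, smap: SnpMap, genotype_path: str | Path, map_path: str | Path
) -> None:
    """Write the TSV dialect (dosage matrix + 3-column map)."""
    with open(map_path, "w") as fh:
        fh.write("marker\tchrom\tpos\n")
        for m, c, p in zip(smap.markers, smap.chroms, smap.positions):
            fh.write(f"{m}\t{c}\t{p}\n")
    with open(genotype_path, "w") as fh:
        fh.write("animal\t" + "\t".join(smap.markers) + "\n")
        for i, animal in enumerate(gm.ids):
            cells = [
                "NA" if v == MISSING else str(int(v)) for v in gm.values[i]
            ]
            fh.write(animal + "\t" + "\t".join(cells) + "\n")


def write_distance_matrix(dm, path: str | Path) -> None:
    """Write a labeled square distance matrix as TSV (12 decimal places)."""
    ids = dm.ids
    values = np.asarray(dm.values, dtype=float)
    if values.size == 0:
        raise ValueError("refusing to write an empty distance matrix")
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i, animal in enumerate(ids):
            fh.write(animal + "\t" + "\t".join(f"{v:.12f}" for v in values[i]) + "\n")


def read_distance_matrix(path: str | Path):
    """Read a labeled square distance matrix written by
    :func:`write_distance_matrix`."""
    from .asd import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != ids:
        raise GenotypeFormatError("distance matrix row/column labels disagree")
    return DistanceMatrix(ids=ids, values=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# informative-SNP filter
# ---------------------------------------------------------------------------


def filter_informative(
    gm: GenotypeMatrix,
    smap: SnpMap,
    maf_min: float = 0.01,
    call_rate_min: float = 0.90,
) -> tuple[GenotypeMatrix, SnpMap, dict]:
    """Retain markers with minor-allele frequency >= ``maf_min`` and call
    rate >= ``call_rate_min``, computed over all animals.

    The thresholds are conventional array QC defaults; the report returned
    alongside records how many markers each criterion removed so the choice
    is auditable.
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if not (0 < call_rate_min <= 1):
        raise ValueError("call_rate_min must be in (0, 1]")
    vals = gm.values
    observed = vals != MISSING
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / max(gm.n_animals, 1)
    with np.errstate(invalid="ignore"):
        p_b = np.where(n_obs > 0, np.where(observed, vals, 0).sum(axis=0) / (2 * np.maximum(n_obs, 1)), 0.0)
    maf = np.minimum(p_b, 1.0 - p_b)
    pass_maf = maf >= maf_min
    pass_call = call_rate >= call_rate_min
    keep = pass_maf & pass_call
    report = {
        "n_input": gm.n_markers,
        "n_retained": int(keep.sum()),
        "n_removed_maf": int((~pass_maf).sum()),
        "n_removed_call_rate": int((~pass_call).sum()),
        "maf_min": maf_min,
        "call_rate_min": call_rate_min,
        "note": (
            "thresholds are package QC defaults; the informative-marker "
            "definition is configurable"
        ),
    }
    if not keep.any():
        raise ValueError(
            "all markers removed by the informative-SNP filter; "
            "lower maf_min / call_rate_min"
        )
    idx = np.flatnonzero(keep)
    smap2 = SnpMap(
        smap.markers[idx],
        smap.chroms[idx],
        smap.positions[idx],
        None if smap.allele_a is None else smap.allele_a[idx],
        None if smap.allele_b is None else smap.allele_b[idx],
    )
    return GenotypeMatrix(gm.ids, vals[:, idx]), smap2, report
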