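"""PLINK binary genotype I/O and the shared in-memory genotype data model.

The central container is :class:`GenotypeDataset`: ordered sample and variant
metadata plus an ``individuals x SNPs`` matrix of allele-1 dosages in
``{0, 1, 2, MISSING}``.  Dosage counts copies of the BIM A1 allele (the PLINK
convention), not a minor allele recomputed from the data, so semantics are
stable across merged sources.

Only SNP-major BED files (the universal modern dialect) are supported; the
legacy individual-major mode raises an explicit error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "Variant",
    "SampleRecord",
    "GenotypeDataset",
    "ClusterAssignmentTable",
    "read_plink",
    "write_plink",
    "read_assignment",
    "write_assignment",
    "read_labels",
    "write_labels",
]

#: Sentinel for a missing genotype in the dosage matrix (stored as int8).
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit BED code -> dosage of allele 1.  Codes are little-endian within the
# byte: sample i at a SNP occupies bits (2*(i%4), 2*(i%4)+1).
#   00 -> 2 copies of A1, 01 -> missing, 10 -> 1 copy, 11 -> 0 copies.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_CHROM_ALIASES = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}
_CHROM_NAMES = {v: k for k, v in _CHROM_ALIASES.items() if k != "M"}


def parse_chromosome(code: str | int) -> int:
    """Normalize a chromosome code to PLINK numeric form.

    1-22 autosomes, X=23, Y=24, XY=25, MT=26, 0=unknown.
    """
    if isinstance(code, (int, np.integer)):
        value = int(code)
    else:
        token = str(code).strip().upper()
        token = re.sub(r"^CHR", "", token)
        if token in _CHROM_ALIASES:
            value = _CHROM_ALIASES[token]
        else:
            try:
                value = int(token)
            except ValueError as exc:
                raise ValueError(f"unrecognized chromosome code: {code!r}") from exc
    if not 0 <= value <= 26:
        raise ValueError(f"chromosome code out of range 0-26: {code!r}")
    return value


def chromosome_name(code: int) -> str:
    return _CHROM_NAMES.get(code, str(code))


@dataclass(frozen=True)
class Variant:
    """One SNP record (a BIM line).

    ``allele1`` is the counted allele (BIM column 5); the dosage matrix counts
    its copies.
    """

    chromosome: int
    position: int
    identifier: str
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"variant {self.identifier}: position must be positive")


@dataclass(frozen=True)
class SampleRecord:
    """One individual (a FAM line) plus an optional reporting-only label."""

    family_id: str
    individual_id: str
    father_id: str = "0"
    mother_id: str = "0"
    sex: int = 0  # 1=male, 2=female, 0=unknown
    population_label: str | None = None

    @property
    def is_founder(self) -> bool:
        """Both parent IDs unknown ("0")."""
        return self.father_id == "0" and self.mother_id == "0"

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.individual_id)


@dataclass
class GenotypeDataset:
    """Samples, variants and the dosage matrix they index.

    ``dosages`` has one row per sample and one column per variant, entries in
    ``{0, 1, 2, MISSING}`` counting copies of each variant's ``allele1``.
    """

    samples: list[SampleRecord]
    variants: list[Variant]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape if self.dosages.ndim == 2 else (len(self.samples), 0)
        if self.dosages.ndim != 2 or n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values: {bad.tolist()}")
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (family_id, individual_id) pairs")
        ids = [v.identifier for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant identifiers")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(
        self,
        sample_indices: Sequence[int] | np.ndarray | None = None,
        variant_indices: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeDataset":
        """New dataset restricted to the given (ordered) indices."""
        si = np.arange(self.n_samples) if sample_indices is None else np.asarray(sample_indices)
        vi = np.arange(self.n_variants) if variant_indices is None else np.asarray(variant_indices)
        return GenotypeDataset(
            samples=[self.samples[i] for i in si],
            variants=[self.variants[j] for j in vi],
            dosages=self.dosages[np.ix_(si, vi)].copy(),
        )

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def population_labels(self) -> list[str | None]:
        return [s.population_label for s in self.samples]

    def with_labels(self, labels: Sequence[str | None]) -> "GenotypeDataset":
        if len(labels) != self.n_samples:
            raise ValueError("one label per sample required")
        samples = [replace(s, population_label=l) for s, l in zip(self.samples, labels)]
        return GenotypeDataset(samples=samples, variants=self.variants, dosages=self.dosages)

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.dosages, other.dosages)
        )


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK binary fileset ``prefix.bed/.bim/.fam``.

    Raises on missing files, bad magic bytes, the unsupported
    individual-major mode, or a truncated genotype block.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for path in (bed_path, bim_path, fam_path):
        if not path.exists():
            raise FileNotFoundError(f"required PLINK file not found: {path}")

    samples = _read_fam(fam_path)
    variants = _read_bim(bim_path)

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise ValueError(f"{bed_path}: not a PLINK BED file (bad magic bytes)")
    if raw[2] != _SNP_MAJOR:
        if raw[2] == 0x00:
            raise ValueError(
                f"{bed_path}: individual-major BED files are not supported"
            )
        raise ValueError(f"{bed_path}: unknown BED mode byte {raw[2]:#04x}")

    n, m = len(samples), len(variants)
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise ValueError(
            f"{bed_path}: truncated or oversized genotype block "
            f"(expected {bytes_per_snp * m} bytes, found {body.size})"
        )
    if m == 0:
        dosages = np.zeros((n, 0), dtype=np.int8)
    else:
        blocks = body.reshape(m, bytes_per_snp)
        # expand each byte to its four 2-bit codes, little-endian within byte
        codes = (blocks[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 0b11
        codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
        dosages = _CODE_TO_DOSAGE[codes].T.copy()
    return GenotypeDataset(samples=samples, variants=variants, dosages=dosages)


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``prefix.bed/.bim/.fam`` (SNP-major); round-trips bit-exactly.

    If any sample carries a population label, a ``prefix.labels.tsv`` is
    written alongside (reporting only; never an input to the analysis).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    _write_fam(dataset.samples, prefix.with_suffix(".fam"))
    _write_bim(dataset.variants, prefix.with_suffix(".bim"))

    n, m = dataset.n_samples, dataset.n_variants
    bytes_per_snp = (n + 3) // 4
    code = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    d = dataset.dosages.T  # m x n
    code[:, :n][d == 2] = 0b00
    code[:, :n][d == 1] = 0b10
    code[:, :n][d == 0] = 0b11
    code[:, :n][d == MISSING] = 0b01
    code[:, n:] = 0b00  # pad bits are zero per PLINK
    packed = (
        code[:, 0::4]
        | (code[:, 1::4] << 2)
        | (code[:, 2::4] << 4)
        | (code[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())

    labels = dataset.population_labels()
    if any(l is not None for l in labels):
        write_labels(dataset, Path(str(prefix) + ".labels.tsv"))


def _read_fam(path: Path) -> list[SampleRecord]:
    samples: list[SampleRecord] = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ValueError(f"{path}: malformed FAM line: {line!r}")
        fid, iid, father, mother, sex = parts[:5]
        samples.append(
            SampleRecord(
                family_id=fid,
                individual_id=iid,
                father_id=father,
                mother_id=mother,
                sex=int(sex) if sex in {"0", "1", "2"} else 0,
            )
        )
    return samples


def _write_fam(samples: Sequence[SampleRecord], path: Path) -> None:
    lines = [
        f"{s.family_id}\t{s.individual_id}\t{s.father_id}\t{s.mother_id}\t{s.sex}\t-9"
        for s in samples
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _read_bim(path: Path) -> list[Variant]:
    variants: list[Variant] = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"{path}: malformed BIM line: {line!r}")
        chrom, ident, _cm, pos, a1, a2 = parts
        variants.append(
            Variant(
                chromosome=parse_chromosome(chrom),
                position=int(pos),
                identifier=ident,
                allele1=a1,
                allele2=a2,
            )
        )
    return variants


def _write_bim(variants: Sequence[Variant], path: Path) -> None:
    lines = [
        f"{chromosome_name(v.chromosome)}\t{v.identifier}\t0\t{v.position}\t{v.allele1}\t{v.allele2}"
        for v in variants
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Truth labels (reporting only)


def write_labels(dataset: GenotypeDataset, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "family_id": [s.family_id for s in dataset.samples],
            "individual_id": [s.individual_id for s in dataset.samples],
            "population": [s.population_label or "" for s in dataset.samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


# ---------------------------------------------------------------------------
# Cluster assignment table


@dataclass
class ClusterAssignmentTable:
    """Per-sample terminal group, outlier flag, and tree node path.

    Backed by a DataFrame with columns
    ``family_id, individual_id, group, outlier, node_path`` in sample order.
    """

    table: pd.DataFrame

    REQUIRED = ("family_id", "individual_id", "group", "outlier", "node_path")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"assignment table missing columns: {sorted(missing)}")
        keys = list(zip(self.table["family_id"], self.table["individual_id"]))
        if len(set(keys)) != len(keys):
            raise ValueError("assignment table lists a sample more than once")
        if (self.table["group"] <= 0).any():
            raise ValueError("group identifiers must be positive integers")

    @property
    def groups(self) -> np.ndarray:
        return self.table["group"].to_numpy()

    @property
    def outlier_flags(self) -> np.ndarray:
        return self.table["outlier"].to_numpy(dtype=bool)

    def accepted_group_ids(self) -> list[int]:
        """Group ids that are not outlier groups, in numeric order."""
        mask = ~self.outlier_flags
        return sorted(set(self.table.loc[mask, "group"].tolist()))

    def members_of(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.table["group"].to_numpy() == group)


def write_assignment(table: ClusterAssignmentTable, path: str | Path) -> None:
    out = table.table.copy()
    out["outlier"] = out["outlier"].astype(bool).map({True: "1", False: "0"})
    out.to_csv(path, sep="\t", index=False)


def read_assignment(path: str | Path) -> ClusterAssignmentTable:
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "individual_id": str, "node_path": str})
    df["group"] = df["group"].astype(int)
    df["outlier"] = df["outlier"].astype(int).astype(bool)
    return ClusterAssignmentTable(table=df)
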