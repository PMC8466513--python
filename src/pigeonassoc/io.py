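"""File dialects and in-silico PCR.

All tables are UTF-8 comma-separated CSV with a header row.  Unknown parents
are empty fields; genotypes are exactly 'AG/AG', 'AG/TT' or 'TT/TT'; a missing
race position means did-not-finish.  Validation errors carry 1-based file line
numbers (header is line 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, MultiProductError, NoProductError
from .pedigree_kinship import Pedigree, PedigreeEntry, RelationshipMatrix
from .popgen import GENOTYPE_LABELS
from .race_scoring import (
    BREEDER_LEVELS,
    SEX_LEVELS,
    WEATHER_END_LEVELS,
    WEATHER_START_LEVELS,
)
from .restriction_assay import Enzyme, _validate_sequence

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, required: list[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")


def _line(idx: int) -> int:
    """File line for DataFrame row ``idx`` (header on line 1)."""
    return idx + 2


def read_pedigree(path: PathLike) -> Pedigree:
    """Read a pedigree CSV (animal_id, sire_id, dam_id, sex)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["animal_id", "sire_id", "dam_id", "sex"], path)
    entries = []
    for idx, row in df.iterrows():
        if not row["animal_id"]:
            raise InputError(f"{path}: line {_line(idx)}: empty animal_id")
        sex = row["sex"] or None
        if sex is not None and sex not in SEX_LEVELS:
            raise InputError(
                f"{path}: line {_line(idx)}: invalid sex {sex!r} (expected {SEX_LEVELS})"
            )
        entries.append(
            PedigreeEntry(
                animal_id=row["animal_id"],
                sire_id=row["sire_id"] or None,
                dam_id=row["dam_id"] or None,
                sex=sex,
            )
        )
    ped = Pedigree(entries)
    log.info("read pedigree: %d animals from %s", len(ped), path)
    return ped


def write_pedigree(ped: Pedigree, path: PathLike) -> None:
    ped.to_dataframe().fillna("").to_csv(path, index=False)


def read_genotypes(path: PathLike) -> pd.DataFrame:
    """Read a genotype CSV (pigeon_id, genotype)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["pigeon_id", "genotype"], path)
    dup = df["pigeon_id"].duplicated()
    if dup.any():
        idx = int(df.index[dup][0])
        raise InputError(
            f"{path}: line {_line(idx)}: duplicate pigeon_id {df.loc[idx, 'pigeon_id']!r}"
        )
    bad = ~df["genotype"].isin(GENOTYPE_LABELS)
    if bad.any():
        idx = int(df.index[bad][0])
        raise InputError(
            f"{path}: line {_line(idx)}: invalid genotype {df.loc[idx, 'genotype']!r} "
            f"(expected one of {GENOTYPE_LABELS})"
        )
    log.info("read genotypes: %d birds from %s", len(df), path)
    return df


def write_genotypes(df: pd.DataFrame, path: PathLike) -> None:
    df[["pigeon_id", "genotype"]].to_csv(path, index=False)


RACE_COLUMNS = [
    "pigeon_id",
    "race_id",
    "distance_km",
    "n_starters",
    "position",
    "weather_start",
    "weather_end",
    "breeder",
    "sex",
]


def read_races(path: PathLike) -> pd.DataFrame:
    """Read a race-record CSV; empty position = did not finish."""
    df = pd.read_csv(path, dtype={"pigeon_id": str, "race_id": str})
    _require_columns(df, RACE_COLUMNS, path)
    df["distance_km"] = pd.to_numeric(df["distance_km"])
    df["n_starters"] = pd.to_numeric(df["n_starters"]).astype(int)
    df["position"] = pd.to_numeric(df["position"]).astype("Int64")
    for col, levels in (
        ("weather_start", WEATHER_START_LEVELS),
        ("weather_end", WEATHER_END_LEVELS),
        ("breeder", BREEDER_LEVELS),
        ("sex", SEX_LEVELS),
    ):
        bad = ~df[col].isin(levels)
        if bad.any():
            idx = int(df.index[bad][0])
            raise InputError(
                f"{path}: line {_line(idx)}: invalid {col} {df.loc[idx, col]!r} "
                f"(expected one of {levels})"
            )
    over = df["position"].notna() & (df["position"] > df["n_starters"])
    if over.any():
        idx = int(df.index[over][0])
        raise InputError(
            f"{path}: line {_line(idx)}: position {df.loc[idx, 'position']} exceeds "
            f"n_starters {df.loc[idx, 'n_starters']}"
        )
    log.info("read races: %d records, %d races from %s",
             len(df), df["race_id"].nunique(), path)
    return df


def write_races(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


def read_fasta(path: PathLike) -> dict[str, str]:
    """FASTA -> {record id: uppercase sequence}."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_enzyme_table(path: PathLike) -> dict[str, Enzyme]:
    """Flat enzyme config CSV: name, recognition, cut_offset."""
    df = pd.read_csv(path, dtype={"name": str, "recognition": str})
    _require_columns(df, ["name", "recognition", "cut_offset"], path)
    enzymes = {}
    for idx, row in df.iterrows():
        try:
            enzymes[row["name"]] = Enzyme(
                name=row["name"],
                recognition=row["recognition"],
                cut_offset=int(row["cut_offset"]),
            )
        except InputError as exc:
            raise InputError(f"{path}: line {_line(idx)}: {exc}") from exc
    return enzymes


def write_relationship_matrix(A: RelationshipMatrix, path: PathLike) -> None:
    A.to_dataframe().to_csv(path)


def read_relationship_matrix(path: PathLike) -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def _mismatch_hits(template: str, primer: str, max_mismatches: int) -> list[tuple[int, int]]:
    """(offset, n_mismatches) of every primer alignment within tolerance."""
    L = len(primer)
    hits = []
    for off in range(len(template) - L + 1):
        mm = sum(a != b for a, b in zip(template[off:off + L], primer))
        if mm <= max_mismatches:
            hits.append((off, mm))
    return hits


def in_silico_pcr(
    template: str, fwd: str, rev: str, max_mismatches: int = 0
) -> str:
    """Predict the PCR product of a primer pair on a template.

    The forward primer is matched on the given strand, the reverse primer as
    its reverse complement.  Among alignments within ``max_mismatches``, the
    pairing with the fewest total mismatches wins; zero candidate pairings or
    several equally good distinct ones are explicit errors.
    """
    template = _validate_sequence(template, "template")
    fwd = _validate_sequence(fwd, "forward primer")
    rev = _validate_sequence(rev, "reverse primer")
    if len(fwd) < 15 or len(rev) < 15:
        raise InputError("primers must be at least 15 nt")
    rc_rev = str(Seq(rev).reverse_complement())
    fwd_hits = _mismatch_hits(template, fwd, max_mismatches)
    rev_hits = _mismatch_hits(template, rc_rev, max_mismatches)
    pairs = [
        (f, r, fm + rm)
        for f, fm in fwd_hits
        for r, rm in rev_hits
        if r >= f + len(fwd)
    ]
    if not pairs:
        raise NoProductError("no amplification product for this primer pair")
    best = min(p[2] for p in pairs)
    winners = [(f, r) for f, r, mm in pairs if mm == best]
    if len(winners) > 1:
        raise MultiProductError(
            f"{len(winners)} equally good products for this primer pair"
        )
    f, r = winners[0]
    return template[f:r + len(rc_rev)]


@dataclass
class PipelineConfig:
    """Paths and options for an end-to-end run, loadable from flat YAML."""

    pedigree: Optional[str] = None
    genotypes: Optional[str] = None
    races: Optional[str] = None
    reference: Optional[str] = None
    enzyme_table: Optional[str] = None
    rounding: str = "floor"
    strict_categories: bool = True
    alpha: float = 0.05
    reml_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InputError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(data) - known
        if unknown:
            raise InputError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("pedigree", "genotypes", "races", "reference", "enzyme_table"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise InputError(f"config path {name} = {value!r} does not exist")
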