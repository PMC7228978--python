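"""ASV count-table and sample-metadata containers, file IO, and global filters.

Counts are stored samples-as-rows in memory but written samples-as-columns
(QIIME convention: one ASV per row, first column the ASV identifier).
ASV identifiers are md5 digests of the 16S sequence; the 4-character display
prefix exists only for figures and is never a join key.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HIV_LEVELS = ("PWH", "SN")
SUBGROUP_LEVELS = ("F", "MSM", "MSW")
RAI_LEVELS = ("RAI+", "RAI-", "unknown")

#: metadata columns that are categorical; missing entries become "unknown"
_CATEGORICAL_COLUMNS = ("hiv_status", "subgroup", "pair_id", "rai", "birth_country")
_NUMERIC_COLUMNS = ("age", "bmi")


@dataclass
class AsvTable:
    """Integer read-count matrix (samples x ASVs) with optional annotations.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one column per ASV id.
    taxonomy
        Optional per-ASV lineage strings, indexed by ASV id.
    sequences
        Optional per-ASV DNA strings, indexed by ASV id.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    sequences: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV ids: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.isfinite(arr).all() or not (arr == np.floor(arr)).all():
                i, j = np.argwhere(~(np.nan_to_num(arr) == np.floor(np.nan_to_num(arr))) | ~np.isfinite(arr))[0]
                raise ValueError(
                    f"non-integer count at sample {c.index[i]!r}, ASV {c.columns[j]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {c.index[i]!r}, ASV {c.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def select_samples(self, sample_ids) -> "AsvTable":
        return AsvTable(self.counts.loc[list(sample_ids)], self.taxonomy, self.sequences)

    def select_asvs(self, asv_ids) -> "AsvTable":
        ids = list(asv_ids)
        return AsvTable(
            self.counts[ids],
            None if self.taxonomy is None else self.taxonomy.loc[ids],
            None if self.sequences is None else self.sequences.loc[ids],
        )


def md5_asv_id(sequence: str) -> tuple[str, str]:
    """Hash a 16S sequence into its full 32-hex ASV id and 4-char display id.

    The sequence is upper-cased before hashing; only A/C/G/T are accepted.
    The display id is for plots only — collisions are possible, so the full
    digest is the internal key.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    full = hashlib.md5(seq.encode("ascii")).hexdigest()
    return full, full[:4]


def filter_rare_asvs(table: AsvTable, min_samples: int = 6) -> AsvTable:
    """Drop ASVs with nonzero counts in fewer than ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    prevalence = (table.counts > 0).sum(axis=0)
    keep = prevalence.index[prevalence >= min_samples]
    dropped = table.n_asvs - len(keep)
    if dropped:
        log.info("filter_rare_asvs: dropped %d of %d ASVs", dropped, table.n_asvs)
    return table.select_asvs(keep)


# ---------------------------------------------------------------------------
# counts IO (TSV, tab-delimited, UTF-8, '#' comment lines ignored)
# ---------------------------------------------------------------------------

def read_counts(path) -> AsvTable:
    """Read an ASVs-x-samples TSV (first column = ASV id) into an AsvTable."""
    with open(path, "r", encoding="utf-8") as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            header = line.rstrip("\n").split("\t")
            break
    if header is None:
        raise ValueError(f"{path}: empty counts file")
    sample_ids = header[1:]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise ValueError(f"{path}: duplicate sample column {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.columns = sample_ids  # undo any pandas de-duplication mangling
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate ASV ids {dups}")
    return AsvTable(df.T)


def write_counts(table: AsvTable, path) -> None:
    """Write counts as an ASVs-x-samples TSV with header row = sample ids."""
    table.counts.T.to_csv(path, sep="\t", index_label="asv_id")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata; missing categoricals become 'unknown'."""
    md = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    if md.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids in metadata")
    for col in _CATEGORICAL_COLUMNS:
        if col not in md.columns:
            continue
        n_missing = md[col].isna().sum()
        if n_missing:
            log.warning("metadata column %r: %d missing values set to 'unknown'", col, n_missing)
            md[col] = md[col].fillna("unknown")
        md[col] = md[col].astype(str)
    for col in _NUMERIC_COLUMNS:
        if col in md.columns:
            md[col] = pd.to_numeric(md[col])
    return md


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def paired_samples(metadata: pd.DataFrame) -> pd.DataFrame:
    """Resolve the case/control matching encoded by ``pair_id``.

    Returns a frame with columns ``pair_id``, ``case_id``, ``control_id``.
    Samples with pair_id 'unknown' are excluded with a logged warning; any
    pair_id not occurring exactly twice, once per hiv_status, is an error.
    """
    md = metadata[metadata["pair_id"] != "unknown"]
    n_excluded = len(metadata) - len(md)
    if n_excluded:
        log.warning("paired_samples: excluding %d samples without a pair id", n_excluded)
    rows = []
    for pid, grp in md.groupby("pair_id", sort=True):
        if len(grp) != 2 or set(grp["hiv_status"]) != set(HIV_LEVELS):
            raise ValueError(
                f"pair {pid!r} must contain exactly one PWH and one SN sample, "
                f"got {grp['hiv_status'].tolist()}"
            )
        case = grp.index[grp["hiv_status"] == "PWH"][0]
        control = grp.index[grp["hiv_status"] == "SN"][0]
        rows.append((pid, case, control))
    return pd.DataFrame(rows, columns=["pair_id", "case_id", "control_id"])


def complete_pair_samples(metadata: pd.DataFrame, sample_ids) -> list:
    """Samples whose matched partner is also in ``sample_ids``.

    Depth filtering can remove one member of a pair; paired analyses then
    exclude the orphaned partner (logged) rather than failing.
    """
    present = set(sample_ids)
    md = metadata.loc[metadata.index.intersection(list(sample_ids))]
    keep = []
    for pid, grp in md.groupby("pair_id", sort=False):
        if pid != "unknown" and len(grp) == 2 and set(grp["hiv_status"]) == set(HIV_LEVELS):
            keep.extend(grp.index)
    dropped = sorted(present - set(keep))
    if dropped:
        log.warning("complete_pair_samples: excluding %d samples without a "
                    "complete pair: %s", len(dropped), dropped)
    return [s for s in sample_ids if s in set(keep)]


# ---------------------------------------------------------------------------
# FASTA for ASV sequences
# ---------------------------------------------------------------------------

def write_fasta(sequences: pd.Series, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for asv_id, seq in sequences.items():
            fh.write(f">{asv_id}\n{seq}\n")


def read_fasta(path) -> pd.Series:
    ids: list[str] = []
    seqs: list[str] = []
    current: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if ids:
                    seqs.append("".join(current))
                ids.append(line[1:].split()[0])
                current = []
            elif line:
                current.append(line)
    if ids:
        seqs.append("".join(current))
    return pd.Series(seqs, index=pd.Index(ids, name="asv_id"), name="sequence")


def summarize(table: AsvTable, metadata: pd.DataFrame | None = None) -> str:
    """Human-readable summary used by the ``validate`` CLI subcommand."""
    totals = table.counts.sum(axis=1)
    lines = [
        f"samples: {table.n_samples}",
        f"ASVs: {table.n_asvs}",
        f"reads/sample: min {totals.min()}, median {int(totals.median())}, max {totals.max()}",
    ]
    if metadata is not None:
        overlap = len(set(table.sample_ids) & set(metadata.index))
        lines.append(f"samples with metadata: {overlap}")
        for col in ("hiv_status", "subgroup", "rai"):
            if col in metadata.columns:
                counts = metadata[col].value_counts().to_dict()
                lines.append(f"{col}: {counts}")
    return "\n".join(lines)
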