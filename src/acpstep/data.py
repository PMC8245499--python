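"""Peptide dataset handling: FASTA I/O, validation and dataset hygiene.

A labelled dataset is a :class:`pandas.DataFrame` with columns
``id`` (unique identifier), ``sequence`` (uppercase, canonical 20-letter
alphabet) and ``label`` (``"ACP"``, ``"nonACP"`` or ``"UNLABELED"``).
The hygiene operations mirror the curation usually applied to activity
benchmarks: a minimum-length filter, exact-duplicate removal including
cross-class conflicts, greedy identity clustering in place of CD-HIT, 1:2
negative subsampling, and a stratified train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import train_test_split

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

ACP = "ACP"
NON_ACP = "nonACP"
UNLABELED = "UNLABELED"

DATASET_COLUMNS = ["id", "sequence", "label"]


@dataclass(frozen=True)
class Peptide:
    """A single identified peptide sequence (uppercased on construction)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


def make_dataset(records, provenance: str = "") -> pd.DataFrame:
    """Build a dataset frame from an iterable of (id, sequence, label)."""
    df = pd.DataFrame(list(records), columns=DATASET_COLUMNS)
    df["sequence"] = df["sequence"].str.upper()
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in dataset: {dups[:5]}")
    df.attrs["provenance"] = provenance
    return df


def read_fasta(path, label_tokens: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a FASTA file into a dataset frame.

    Labels are parsed from a header token; by default a header ending in
    ``|ACP`` or ``|nonACP`` carries the class, anything else is UNLABELED.

    Parameters
    ----------
    path : str or Path
        FASTA file (wrapped or unwrapped lines).
    label_tokens : dict, optional
        Mapping from header suffix token to label, default
        ``{"ACP": "ACP", "nonACP": "nonACP"}`` matched after the last ``|``.
    """
    if label_tokens is None:
        label_tokens = {"ACP": ACP, "nonACP": NON_ACP}
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        label = UNLABELED
        if "|" in header:
            token = header.rsplit("|", 1)[1]
            label = label_tokens.get(token, UNLABELED)
        rows.append((header, str(rec.seq).upper(), label))
    if not rows:
        warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
        return make_dataset([], provenance=str(path))
    return make_dataset(rows, provenance=str(path))


def write_fasta(ds: pd.DataFrame, path) -> None:
    """Write a dataset to FASTA; labels already embedded in ids are kept,
    otherwise the ``|<label>`` suffix convention is appended."""
    records = []
    for row in ds.itertuples(index=False):
        header = row.id
        if row.label != UNLABELED and not header.endswith(f"|{row.label}"):
            header = f"{header}|{row.label}"
        records.append(SeqRecord(Seq(row.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def validate_peptide(sequence: str, min_length: int = 11) -> tuple[bool, str | None]:
    """Accept a sequence iff it is canonical-alphabet and at least
    ``min_length`` residues long (default keeps peptides longer than 10).

    Returns ``(True, None)`` or ``(False, reason)`` with reason in
    ``{"NON_CANONICAL", "TOO_SHORT"}``.
    """
    if not set(sequence.upper()) <= _CANONICAL_SET or not sequence:
        return False, "NON_CANONICAL"
    if len(sequence) < min_length:
        return False, "TOO_SHORT"
    return True, None


def filter_valid(ds: pd.DataFrame, min_length: int = 11) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a dataset into accepted records and rejected records.

    The rejected frame carries an extra ``reason`` column.
    """
    verdicts = ds["sequence"].map(lambda s: validate_peptide(s, min_length))
    ok = verdicts.map(lambda v: v[0])
    accepted = ds[ok].reset_index(drop=True)
    rejected = ds[~ok].copy()
    rejected["reason"] = verdicts[~ok].map(lambda v: v[1]).values
    return accepted, rejected.reset_index(drop=True)


def deduplicate_exact(ds: pd.DataFrame) -> pd.DataFrame:
    """Remove exact-sequence duplicates; first seen wins within a class.

    A sequence present in both classes is removed from BOTH (cross-class
    100 %-identity exclusion), since a conflicting label makes the record
    unusable for training.
    """
    by_seq = ds.groupby("sequence")["label"].nunique()
    conflicted = set(by_seq[by_seq > 1].index)
    kept = ds[~ds["sequence"].isin(conflicted)]
    kept = kept.drop_duplicates(subset=["sequence", "label"], keep="first")
    return kept.reset_index(drop=True)


def _identity_aligner(match: float = 1.0, mismatch: float = 0.0, gap: float = 0.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment sequence identity between two peptides.

    Identity = (maximum number of matched columns under global alignment
    with match=1, mismatch=0, zero gap cost) / max(len(a), len(b)).  With
    zero gap cost co-optimal alignments differ in column count, so the
    longer sequence length is used as the stable denominator (gaps then
    only pad the shorter sequence).
    """
    if aligner is None:
        aligner = _identity_aligner()
    matches = aligner.score(a, b)
    return matches / max(len(a), len(b))


def greedy_cluster_identity(ds: pd.DataFrame, identity_threshold: float = 0.90) -> pd.DataFrame:
    """Greedy redundancy reduction at a sequence-identity threshold.

    Sequences are visited longest-first (ties broken by id) and a record is
    discarded when its identity to any already-retained representative of
    the same class reaches the threshold.  This reproduces the intent of
    CD-HIT clustering deterministically, without its k-mer heuristics.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    aligner = _identity_aligner()
    keep_rows = []
    for label, sub in ds.groupby("label", sort=False):
        ordered = sub.sort_values(
            by=["sequence", "id"],
            key=lambda col: -col.str.len() if col.name == "sequence" else col,
        )
        reps: list[str] = []
        for row in ordered.itertuples():
            if any(pairwise_identity(row.sequence, r, aligner) >= identity_threshold for r in reps):
                continue
            reps.append(row.sequence)
            keep_rows.append(row.Index)
    kept = ds.loc[sorted(keep_rows)]
    return kept.reset_index(drop=True)


def sample_negatives(
    pos: pd.DataFrame, neg_pool: pd.DataFrame, ratio: float = 2.0, seed: int = 0
) -> pd.DataFrame:
    """Combine all positives with ``round(ratio * n_pos)`` negatives sampled
    without replacement from the pool (default 1:2 positive:negative)."""
    n_needed = int(round(ratio * len(pos)))
    if len(neg_pool) < n_needed:
        raise ValueError(
            f"negative pool has {len(neg_pool)} records but {n_needed} are required"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(neg_pool), size=n_needed, replace=False)
    chosen = neg_pool.iloc[np.sort(idx)]
    return pd.concat([pos, chosen], ignore_index=True)


def split_train_test(
    ds: pd.DataFrame, test_fraction: float, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label-stratified, seed-reproducible train/test partition."""
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    counts = ds["label"].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each label needs at least 2 records to stratify")
    train, test = train_test_split(
        ds,
        test_size=test_fraction,
        random_state=seed,
        stratify=ds["label"],
        shuffle=True,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def write_manifest(ds: pd.DataFrame, path) -> None:
    """Write a TSV manifest (id, label, length) for a dataset."""
    out = ds.assign(length=ds["sequence"].str.len())[["id", "label", "length"]]
    out.to_csv(path, sep="\t", index=False)
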