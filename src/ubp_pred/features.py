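"""Composition and profile features: the 820-dimensional protein encoding.

A protein is encoded as the concatenation of three blocks:

* **AAC** (20 dims): amino-acid composition, the fraction of each of the 20
  standard residues in the sequence; sums to 1.
* **DC** (400 dims): dipeptide composition, the fraction of each ordered
  adjacent residue pair among the L-1 pairs; sums to 1.
* **PSSM-composition** (400 dims): for each (residue t, profile column c)
  pair, the sum of the column-c scores over the positions occupied by
  residue t in the PSI-BLAST profile.  These are raw sums by default; an
  optional normalization divides by sequence length or per-residue count.

Feature names use the canonical alphabetical residue order
(``A, C, D, ..., Y``): ``AAC:A``, ``DC:AC``, ``PSSM:A|C`` (residue-row A,
profile-column C).  The PSSM file's own column order is mapped onto this
canonical order via ``PssmMatrix.column_order``, so file layout is a
recorded contract rather than an assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ubp_pred.io_formats import STANDARD_AA, ProteinRecord, PssmMatrix

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

PSSM_NORMALIZATIONS = ("none", "by_length", "by_residue_count")


def aac_names() -> list[str]:
    return [f"AAC:{a}" for a in STANDARD_AA]


def dc_names() -> list[str]:
    return [f"DC:{a}{b}" for a in STANDARD_AA for b in STANDARD_AA]


def pssm_names() -> list[str]:
    return [f"PSSM:{t}|{c}" for t in STANDARD_AA for c in STANDARD_AA]


def feature_names(include_pssm: bool = True) -> list[str]:
    names = aac_names() + dc_names()
    if include_pssm:
        names += pssm_names()
    return names


@dataclass
class FeatureVector:
    """One protein's ordered feature values with aligned names."""

    protein_id: str
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")


@dataclass
class FeatureMatrix:
    """A stacked n x d feature matrix with row ids and optional 0/1 labels."""

    ids: list[str]
    names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.ids), len(self.names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.names)} names"
            )
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.ids),):
                raise ValueError("labels must align with ids")
            if not np.isin(self.labels, [0, 1]).all():
                raise ValueError("labels must be 0/1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def select_features(self, names: list[str]) -> "FeatureMatrix":
        """Column subset (and reordering) by feature name."""
        missing = [n for n in names if n not in self.names]
        if missing:
            raise KeyError(f"unknown feature names: {missing[:5]}")
        idx = [self.names.index(n) for n in names]
        return FeatureMatrix(self.ids, list(names), self.values[:, idx], self.labels)

    def select_rows(self, row_idx: np.ndarray) -> "FeatureMatrix":
        ids = [self.ids[i] for i in row_idx]
        labels = self.labels[row_idx] if self.labels is not None else None
        return FeatureMatrix(ids, self.names, self.values[row_idx], labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.names)
        df.index.name = "id"
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), labels)


# ---------------------------------------------------------------------------
# Feature blocks


def _check_standard(record: ProteinRecord) -> None:
    if not record.is_standard():
        bad = sorted(set(record.sequence) - set(STANDARD_AA))
        raise ValueError(
            f"protein {record.id!r} contains nonstandard residues {bad}; "
            "run apply_dataset_filters first"
        )


def compute_aac(record: ProteinRecord) -> np.ndarray:
    """Amino-acid composition: count of each residue divided by length L."""
    _check_standard(record)
    counts = np.zeros(20)
    for ch in record.sequence:
        counts[_AA_INDEX[ch]] += 1
    return counts / record.length


def compute_dc(record: ProteinRecord) -> np.ndarray:
    """Dipeptide composition: ordered adjacent-pair counts divided by L-1.

    Pair order is row-major over the canonical residue order, matching
    :func:`dc_names`.
    """
    _check_standard(record)
    if record.length < 2:
        raise ValueError(f"sequence_too_short_for_dc: {record.id!r} has length 1")
    counts = np.zeros((20, 20))
    seq = record.sequence
    for a, b in zip(seq, seq[1:]):
        counts[_AA_INDEX[a], _AA_INDEX[b]] += 1
    return counts.ravel() / (record.length - 1)


def compute_pssm_composition(
    record: ProteinRecord, pssm: PssmMatrix, normalize: str = "none"
) -> np.ndarray:
    """PSSM-composition: profile columns summed by the residue at each position.

    Component (t, c) is the sum of ``scores[p, column c]`` over positions p
    whose sequence residue is t — the standard 400-dimensional reduction of
    an L x 20 profile to a length-independent vector.  Components are laid
    out row-major over (t, c) in canonical residue order, matching
    :func:`pssm_names`.

    ``normalize`` is ``"none"`` (raw sums, default), ``"by_length"``
    (divide all components by L) or ``"by_residue_count"`` (divide row t by
    the count of residue t in the sequence).
    """
    _check_standard(record)
    if normalize not in PSSM_NORMALIZATIONS:
        raise ValueError(f"unknown normalization {normalize!r}")
    pssm.check_sequence(record)

    # Map the file's column order onto canonical alphabetical order.
    col_perm = np.array([pssm.column_order.index(a) for a in STANDARD_AA])
    scores = pssm.scores[:, col_perm]  # L x 20 in canonical column order

    out = np.zeros((20, 20))
    row_idx = np.fromiter((_AA_INDEX[ch] for ch in record.sequence), dtype=int)
    np.add.at(out, row_idx, scores)

    if normalize == "by_length":
        out /= record.length
    elif normalize == "by_residue_count":
        counts = np.bincount(row_idx, minlength=20).astype(float)
        nonzero = counts > 0
        out[nonzero] /= counts[nonzero, None]
    return out.ravel()


def featurize(
    record: ProteinRecord,
    pssm: PssmMatrix | None = None,
    include_pssm: bool = True,
    pssm_normalize: str = "none",
) -> FeatureVector:
    """Encode one protein as the AAC + DC (+ PSSM-composition) concatenation.

    With ``include_pssm`` the result is 820-dimensional (20 + 400 + 400);
    without it, 420.  A missing PSSM while the block is requested is an
    error rather than an imputed zero block.
    """
    blocks = [compute_aac(record), compute_dc(record)]
    if include_pssm:
        if pssm is None:
            raise ValueError(
                f"protein {record.id!r}: PSSM block requested but no PSSM supplied"
            )
        blocks.append(compute_pssm_composition(record, pssm, normalize=pssm_normalize))
    return FeatureVector(
        protein_id=record.id,
        values=np.concatenate(blocks),
        names=feature_names(include_pssm=include_pssm),
    )


def build_feature_matrix(
    records: list[ProteinRecord],
    pssms: dict[str, PssmMatrix] | None = None,
    labels: dict[str, int] | None = None,
    include_pssm: bool = True,
    pssm_normalize: str = "none",
) -> FeatureMatrix:
    """Featurize a dataset into one stacked matrix with aligned labels."""
    vectors = []
    for rec in records:
        pssm = None
        if include_pssm:
            if pssms is None or rec.id not in pssms:
                raise KeyError(f"no PSSM supplied for protein {rec.id!r}")
            pssm = pssms[rec.id]
        vectors.append(featurize(rec, pssm, include_pssm, pssm_normalize))
    ids = [v.protein_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in dataset")
    values = np.vstack([v.values for v in vectors])
    y = None
    if labels is not None:
        missing = [i for i in ids if i not in labels]
        if missing:
            raise KeyError(f"no label for proteins: {missing[:5]}")
        y = np.array([labels[i] for i in ids], dtype=int)
    return FeatureMatrix(ids, feature_names(include_pssm=include_pssm), values, y)
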