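"""Synthetic data generators for every input the pipeline consumes.

These generators exist so the full pipeline — featurization, selection,
tuning, classification, enrichment, window extraction — can be exercised
end-to-end without external databases or a PSI-BLAST run.  They emulate the
*shape* of real inputs (random 20-letter protein sequences of length >= 50,
L x 20 profile matrices written in the BLAST+ ASCII dialect, balanced
two-class datasets, GMT annotation universes, binding-site tables), with a
*planted* class signal whose strength is controlled by a single effect
size.

The planted signal lives in composition space rather than motif space: the
positive class draws residues from a mixture ``(1 - e) * uniform +
e * biased`` over a designated residue subset (``aac_bias``), or receives a
shifted profile column (``pssm_bias``).  Because the classifier consumes
composition features, this makes signal-recovery tests direct: at effect
size 0 the two classes are exchangeable and any cross-validated MCC near 0
is correct behavior; at effect size 0.8 the classes are cleanly separable
and a working pipeline must recover MCC near 1.

Every generator is a pure function of its configuration (seeded NumPy
generators), so identical configs yield identical datasets.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ubp_pred.features import FeatureMatrix, build_feature_matrix
from ubp_pred.io_formats import (
    STANDARD_AA,
    AnnotationSet,
    ProteinRecord,
    PssmMatrix,
    write_annotations,
    write_fasta,
    write_labels,
    write_pssm,
    write_sites,
)

SIGNAL_KINDS = ("aac_bias", "dc_bias", "pssm_bias", "none")

#: Residues up-weighted in the positive class under ``aac_bias``.
DEFAULT_BIAS_RESIDUES = ("A", "C", "D")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated two-class protein dataset."""

    seed: int = 0
    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (50, 80)
    signal_kind: str = "none"
    effect_size: float = 0.0
    bias_residues: tuple[str, ...] = DEFAULT_BIAS_RESIDUES

    def __post_init__(self) -> None:
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal_kind {self.signal_kind!r}")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must be in [0, 1]")
        if self.length_range[0] < 50:
            raise ValueError("minimum length must be >= 50 (dataset filter boundary)")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be (min, max) with min <= max")


def _residue_distribution(config: SyntheticConfig, positive: bool) -> np.ndarray:
    """Per-class residue sampling distribution over the canonical order."""
    uniform = np.full(20, 1 / 20)
    if not positive or config.signal_kind not in ("aac_bias", "dc_bias"):
        return uniform
    biased = np.zeros(20)
    for aa in config.bias_residues:
        biased[STANDARD_AA.index(aa)] = 1 / len(config.bias_residues)
    return (1 - config.effect_size) * uniform + config.effect_size * biased


def generate_proteins(config: SyntheticConfig) -> list[ProteinRecord]:
    """Draw ``n_pos + n_neg`` random proteins, positives first.

    Ids are ``pos0001..`` / ``neg0001..``; lengths are uniform over
    ``length_range``.  Under ``aac_bias`` the positive class up-weights the
    designated residues by the effect size; under ``dc_bias`` positives
    additionally repeat biased residues in adjacent pairs, shifting
    dipeptide composition beyond what the residue marginals explain.
    """
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(STANDARD_AA))
    records: list[ProteinRecord] = []
    for positive, count, prefix in (
        (True, config.n_pos, "pos"),
        (False, config.n_neg, "neg"),
    ):
        dist = _residue_distribution(config, positive)
        for i in range(count):
            length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
            letters = rng.choice(aa, size=length, p=dist)
            if positive and config.signal_kind == "dc_bias" and config.effect_size > 0:
                # Duplicate biased residues into their right neighbor with
                # probability = effect size, planting pair-level structure.
                for p in range(length - 1):
                    if letters[p] in config.bias_residues and rng.uniform() < config.effect_size:
                        letters[p + 1] = letters[p]
            records.append(ProteinRecord(f"{prefix}{i + 1:04d}", "".join(letters)))
    return records


def generate_pssm(
    record: ProteinRecord,
    config: SyntheticConfig,
    positive: bool | None = None,
    path: str | Path | None = None,
) -> PssmMatrix:
    """Generate an integer log-odds-like profile for one protein.

    Background scores are integers in [-5, 5]; the column of the residue
    actually at each position is up-shifted (+4), mimicking the
    self-conservation structure of real profiles.  Under ``pssm_bias`` for
    positive-class proteins, the columns of the designated residues are
    further shifted by ``round(6 * effect_size)``, which separates the
    classes in PSSM-composition space.

    When ``path`` is given, the matrix is also written in the BLAST+ ASCII
    dialect (parseable by :func:`ubp_pred.io_formats.read_pssm`).
    The per-protein seed is derived from the config seed and the protein id,
    so regeneration of any single profile is reproducible.
    """
    if positive is None:
        positive = record.id.startswith("pos")
    # Stable per-protein stream independent of generation order (crc32 is
    # deterministic across processes, unlike builtin str hashing).
    sub_seed = np.random.SeedSequence([config.seed, zlib.crc32(record.id.encode())])
    rng = np.random.default_rng(sub_seed)
    length = record.length
    scores = rng.integers(-5, 6, size=(length, 20)).astype(float)
    row_idx = np.array([STANDARD_AA.index(ch) for ch in record.sequence])
    scores[np.arange(length), row_idx] += 4
    if positive and config.signal_kind == "pssm_bias" and config.effect_size > 0:
        shift = round(6 * config.effect_size)
        for residue in config.bias_residues:
            scores[:, STANDARD_AA.index(residue)] += shift
    matrix = PssmMatrix(
        protein_id=record.id,
        scores=scores,
        column_order=STANDARD_AA,
        source_kind="log_odds",
        row_residues=record.sequence,
    )
    if path is not None:
        # Percent block: per-row softmax-like frequencies, so the
        # percent_frequency reader has something meaningful to return.
        exp = np.exp(scores / 4.0)
        write_pssm(matrix, path, percents=exp / exp.sum(axis=1, keepdims=True))
    return matrix


def generate_labeled_dataset(
    config: SyntheticConfig,
    pssm_dir: str | Path | None = None,
) -> FeatureMatrix:
    """End-to-end: proteins -> profiles -> 820-dim features -> labeled matrix.

    Positives are labeled 1.  When ``pssm_dir`` is given, each profile is
    also written as an ASCII file there.
    """
    records = generate_proteins(config)
    pssms = {}
    for rec in records:
        path = None
        if pssm_dir is not None:
            Path(pssm_dir).mkdir(parents=True, exist_ok=True)
            path = Path(pssm_dir) / f"{rec.id}.pssm"
        pssms[rec.id] = generate_pssm(rec, config, path=path)
    labels = {rec.id: 1 if rec.id.startswith("pos") else 0 for rec in records}
    return build_feature_matrix(records, pssms, labels)


def generate_annotation_universe(
    seed: int = 0,
    n_genes: int = 200,
    n_terms: int = 40,
    term_size_range: tuple[int, int] = (5, 30),
    query_size: int = 20,
    planted_term_overlap: int = 15,
) -> tuple[AnnotationSet, set[str], str]:
    """Random annotation universe with one planted enriched term.

    Terms ``T0001..`` get uniformly random gene sets.  A dedicated planted
    term ``T_planted`` shares ``planted_term_overlap`` genes with the query
    (the rest of the query is random), so by construction it attains the
    largest overlap and the smallest hypergeometric P-value in expectation.

    Returns ``(annotations, query, planted_term_id)``.
    """
    if planted_term_overlap > query_size:
        raise ValueError("planted overlap cannot exceed the query size")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    term_to_genes: dict[str, frozenset[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        members = rng.choice(genes, size=size, replace=False)
        term_to_genes[f"T{t + 1:04d}"] = frozenset(members)

    query = set(rng.choice(genes, size=query_size, replace=False))
    planted_members = set(rng.choice(sorted(query), size=planted_term_overlap, replace=False))
    # Pad the planted term with a few non-query genes so it is not the query itself.
    outside = [g for g in genes if g not in query]
    planted_members |= set(rng.choice(outside, size=5, replace=False))
    term_to_genes["T_planted"] = frozenset(planted_members)

    annotations = AnnotationSet(term_to_genes, frozenset(genes))
    return annotations, query, "T_planted"


def generate_sites(
    records: list[ProteinRecord], seed: int = 0, sites_per_protein: int = 1
) -> list[tuple[str, int]]:
    """Uniform random binding-site positions, one table row per site."""
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        for _ in range(sites_per_protein):
            rows.append((rec.id, int(rng.integers(1, rec.length + 1))))
    return rows


@dataclass
class ToyProject:
    """Paths of a generated toy project directory."""

    root: Path
    fasta: Path
    pssm_dir: Path
    labels: Path
    annotations: Path
    sites: Path
    extras: dict = field(default_factory=dict)


def write_toy_project(directory: str | Path, config: SyntheticConfig) -> ToyProject:
    """Emit a complete toy project: FASTA, PSSM dir, labels, GMT, sites.

    The annotation universe uses the protein ids as its gene universe with
    a planted term over positive-class proteins, so the enrichment stage
    can be demonstrated on the same toy data.
    """
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    records = generate_proteins(config)

    fasta = root / "proteins.fasta"
    write_fasta(records, fasta)

    pssm_dir = root / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for rec in records:
        generate_pssm(rec, config, path=pssm_dir / f"{rec.id}.pssm")

    labels_path = root / "labels.tsv"
    write_labels(
        {rec.id: 1 if rec.id.startswith("pos") else 0 for rec in records}, labels_path
    )

    rng = np.random.default_rng(config.seed + 1)
    pos_ids = [r.id for r in records if r.id.startswith("pos")]
    all_ids = [r.id for r in records]
    term_to_genes = {
        "T_positive": frozenset(rng.choice(pos_ids, size=min(20, len(pos_ids)), replace=False)),
    }
    random_term_size = min(15, max(2, len(all_ids) // 3))
    for t in range(10):
        members = rng.choice(all_ids, size=random_term_size, replace=False)
        term_to_genes[f"T{t + 1:04d}"] = frozenset(members)
    annotations = AnnotationSet(term_to_genes, frozenset(all_ids))
    gmt = root / "terms.gmt"
    write_annotations(annotations, gmt)

    sites_path = root / "sites.tsv"
    write_sites(generate_sites(records, seed=config.seed + 2), sites_path)

    return ToyProject(
        root=root,
        fasta=fasta,
        pssm_dir=pssm_dir,
        labels=labels_path,
        annotations=gmt,
        sites=sites_path,
    )


def null_config(config: SyntheticConfig) -> SyntheticConfig:
    """The matched no-signal control of a planted-signal configuration."""
    return replace(config, signal_kind="none", effect_size=0.0)
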