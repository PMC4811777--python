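"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate, at desk scale, the data the pipeline consumes in a
real study: a small bead-array-like expression matrix with technical
duplicates and planted log2 fold changes; a GBM-style centroid signature and
a cross-species gene-symbol map; an ordered SNP-marker track with injected
copy-number segments, a GC-correlated LRR wave and cluster-structured BAF;
and a cohort of expression z-scores with a planted group shift.

All generators are pure functions of their parameters and a seed: every
draw goes through :func:`numpy.random.default_rng` (PCG64), so repeated
calls with identical arguments are bit-identical across platforms. The
returned truth objects (:class:`ExpressionTruth`, :class:`CnvTruth`) carry
everything needed to score downstream recovery — planted gene sets,
segment coordinates and states — without re-deriving anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gbmkit.expression import ExpressionMatrix, SampleAnnotation

__all__ = [
    "ExpressionTruth",
    "CnvTruth",
    "CnvSegment",
    "DEFAULT_SUBTYPE_PROBS",
    "gen_expression",
    "gen_centroids",
    "gen_gene_map",
    "gen_marker_track",
    "gen_cohort",
]

#: Default categorical distribution of GBM subtype labels in generated
#: cohorts; proportions chosen to resemble published subtype frequencies
#: (Proneural-rich, G-CIMP rare).
DEFAULT_SUBTYPE_PROBS = {
    "GCiMP": 0.05,
    "Proneural": 0.30,
    "Neural": 0.15,
    "Classical": 0.25,
    "Mesenchymal": 0.25,
}


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionTruth:
    """Ground truth for a generated expression matrix.

    ``planted_logfc`` maps each non-reference condition to a gene→log2 fold
    change dict; ``signature_subtype`` optionally records which subtype
    centroid pattern the fold changes encode; ``noise_sd`` is the SD of the
    additive technical noise on the log2 scale.
    """

    planted_logfc: dict[str, dict[str, float]] = field(default_factory=dict)
    signature_subtype: str | None = None
    noise_sd: float = 0.1
    seed: int = 0


def gen_expression(
    n_genes: int,
    conditions: dict[str, int],
    n_tech_dups: int,
    truth: ExpressionTruth,
    reference: str | None = None,
    baseline_mean: float = 7.0,
    baseline_sd: float = 2.0,
    gene_ids=None,
) -> tuple[ExpressionMatrix, SampleAnnotation, ExpressionTruth]:
    """Generate a raw-intensity bead-array-like matrix with technical duplicates.

    The gene universe defaults to ``g0001..g{n_genes}``; ``gene_ids`` can
    replace any prefix of it (e.g. to seat signature genes in the matrix),
    with generated filler names completing the count. Each condition contributes
    ``conditions[name]`` biological samples; each biological sample is a
    latent log2 vector (gene baseline + planted condition effect) and is
    measured ``n_tech_dups`` times with independent N(0, ``noise_sd``) noise,
    so duplicate pairs share the latent sample exactly. Emitted intensities
    are ``2**log2`` and hence strictly positive; planted log2 fold changes
    hold in expectation for every non-reference condition.

    Returns the raw matrix, a sample annotation (condition +
    replicate-group ids), and the truth object passed in.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if n_tech_dups < 1:
        raise ValueError("n_tech_dups must be positive")
    if not conditions:
        raise ValueError("need at least one condition")
    reference = reference if reference is not None else next(iter(conditions))
    if reference not in conditions:
        raise ValueError(f"reference condition {reference!r} not in conditions")

    named = [str(g) for g in gene_ids] if gene_ids is not None else []
    if len(named) > n_genes:
        raise ValueError("more gene_ids than n_genes")
    genes = named + [f"g{i:04d}" for i in range(1, n_genes - len(named) + 1)]
    gene_set = set(genes)
    if len(gene_set) != len(genes):
        raise ValueError("gene_ids collide with generated filler names")
    for condition, effects in truth.planted_logfc.items():
        if condition not in conditions:
            raise ValueError(f"planted condition {condition!r} not in conditions")
        for gene in effects:
            if gene not in gene_set:
                raise ValueError(f"planted gene {gene!r} not in the gene universe")

    rng = np.random.default_rng(truth.seed)
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)

    columns: dict[str, np.ndarray] = {}
    ann_rows = []
    for condition, n_samples in conditions.items():
        if n_samples < 1:
            raise ValueError(f"condition {condition!r} needs >= 1 sample")
        effect = np.zeros(n_genes)
        for gene, logfc in truth.planted_logfc.get(condition, {}).items():
            effect[genes.index(gene)] = logfc
        if condition == reference and truth.planted_logfc.get(condition):
            raise ValueError("cannot plant fold changes on the reference condition")
        for s in range(1, n_samples + 1):
            latent = baseline + effect
            group = f"{condition}_s{s}"
            for t in range(1, n_tech_dups + 1):
                noise = (
                    rng.normal(0.0, truth.noise_sd, size=n_genes)
                    if truth.noise_sd > 0
                    else np.zeros(n_genes)
                )
                sample_id = f"{group}_t{t}"
                columns[sample_id] = np.power(2.0, latent + noise)
                ann_rows.append(
                    {
                        "sample_id": sample_id,
                        "condition": condition,
                        "replicate_group": group,
                    }
                )

    matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=pd.Index(genes, name="gene")), scale="raw"
    )
    annotation = SampleAnnotation(pd.DataFrame(ann_rows), reference=reference)
    return matrix, annotation, truth


def gen_centroids(
    n_genes: int = 60,
    subtypes=("Classical", "Mesenchymal", "Neural", "Proneural"),
    scale: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic signature-gene x subtype centroid matrix.

    Centroid values are independent N(0, ``scale``) draws per gene and
    subtype — a stand-in signature with the same shape as a published
    GBM centroid set, suitable for planted-truth recovery tests.
    Signature genes are upper-case (human-style) symbols ``SIG0001..``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"SIG{i:04d}" for i in range(1, n_genes + 1)]
    values = rng.normal(0.0, scale, size=(n_genes, len(subtypes)))
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=list(subtypes))


def gen_gene_map(
    target_genes,
    mapped_fraction: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Mouse→human-style symbol map covering a fraction of the target genes.

    Source symbols are the capitalized form of the targets (human ``SIG0001``
    → mouse ``Sig0001``), the usual orthographic convention between the two
    species; a random ``1 - mapped_fraction`` of targets is left unmapped to
    emulate incomplete ortholog correspondence.
    """
    if not 0 < mapped_fraction <= 1:
        raise ValueError("mapped_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    targets = list(target_genes)
    n_keep = max(1, int(round(mapped_fraction * len(targets))))
    keep = sorted(rng.choice(len(targets), size=n_keep, replace=False))
    rows = [
        {"source": targets[i].capitalize(), "target": targets[i]} for i in keep
    ]
    return pd.DataFrame(rows, columns=["source", "target"])


# ---------------------------------------------------------------------------
# marker track
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int
    end: int
    state: int
    shift: float


@dataclass(frozen=True)
class CnvTruth:
    """Planted copy-number segments plus wave and noise parameters.

    ``segments`` must be non-overlapping within a chromosome with integer
    states in [0, 4]; ``wave_coefficient`` is in LRR units per unit of
    (GC fraction - median GC); ``noise_sd`` is the marker-level LRR noise.
    """

    segments: tuple[CnvSegment, ...] = ()
    wave_coefficient: float = 0.0
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[CnvSegment]] = {}
        for seg in self.segments:
            if not 0 <= seg.state <= 4 or int(seg.state) != seg.state:
                raise ValueError(f"state must be an integer in [0, 4], got {seg.state}")
            if seg.end < seg.start:
                raise ValueError(f"segment end before start: {seg}")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for left, right in zip(segs[:-1], segs[1:]):
                if right.start <= left.end:
                    raise ValueError(
                        f"overlapping truth segments on {chrom}: "
                        f"{(left.start, left.end)} and {(right.start, right.end)}"
                    )


#: BAF cluster centres by copy-number state (genotype allele ratios).
_BAF_CLUSTERS = {
    0: (0.5,),  # no signal: mid-range noise
    1: (0.0, 1.0),
    2: (0.0, 0.5, 1.0),
    3: (0.0, 1 / 3, 2 / 3, 1.0),
    4: (0.0, 0.25, 0.5, 0.75, 1.0),
}


def _smooth_gc(rng, n: int, lo: float = 0.3, hi: float = 0.7) -> np.ndarray:
    """Smoothed random walk clipped to [lo, hi] — a bounded, spatially smooth GC track."""
    walk = np.cumsum(rng.normal(0.0, 0.01, size=n)) + 0.5
    if n >= 3:
        window = max(3, min(51, (n // 10) | 1))
        kernel = np.ones(window) / window
        walk = np.convolve(np.pad(walk, window // 2, mode="edge"), kernel, mode="valid")[:n]
    return np.clip(walk, lo, hi)


def gen_marker_track(
    chrom_lengths: dict[str, int],
    marker_spacing: int,
    truth: CnvTruth,
    baf_noise_sd: float = 0.03,
) -> tuple[pd.DataFrame, CnvTruth]:
    """Generate an ordered SNP-marker track with planted CNVs and a GC wave.

    Markers sit at ``spacing, 2*spacing, ...`` up to each chromosome length,
    so a 100 Mb chromosome at 50 kb spacing yields exactly 2000 markers.
    Per marker: ``LRR = shift(covering truth segment) + wave_coefficient *
    (GC - median GC) + N(0, noise_sd)``; GC fractions come from a smoothed
    random walk clipped to [0.3, 0.7]; BAF is drawn around the genotype
    cluster centres of the covering state (e.g. {0, 0.5, 1} for the normal
    state) and clipped to [0, 1]. All markers probe allelic balance.
    """
    if marker_spacing <= 0:
        raise ValueError("marker_spacing must be positive")
    for seg in truth.segments:
        if seg.chrom not in chrom_lengths:
            raise ValueError(f"truth segment on unknown chromosome {seg.chrom!r}")
        if seg.start < 1 or seg.end > chrom_lengths[seg.chrom]:
            raise ValueError(f"truth segment outside chromosome bounds: {seg}")

    rng = np.random.default_rng(truth.seed)
    frames = []
    for chrom, length in chrom_lengths.items():
        n = length // marker_spacing
        if n == 0:
            continue
        pos = np.arange(1, n + 1) * marker_spacing
        gc = _smooth_gc(rng, n)
        shift = np.zeros(n)
        state = np.full(n, 2, dtype=int)
        for seg in truth.segments:
            if seg.chrom != chrom:
                continue
            inside = (pos >= seg.start) & (pos <= seg.end)
            shift[inside] = seg.shift
            state[inside] = seg.state
        lrr = shift + truth.wave_coefficient * (gc - np.median(gc))
        if truth.noise_sd > 0:
            lrr = lrr + rng.normal(0.0, truth.noise_sd, size=n)
        baf = np.empty(n)
        for i in range(n):
            centres = _BAF_CLUSTERS[int(state[i])]
            centre = centres[rng.integers(len(centres))]
            jitter = rng.normal(0.0, baf_noise_sd) if baf_noise_sd > 0 else 0.0
            baf[i] = min(1.0, max(0.0, centre + jitter))
        frames.append(
            pd.DataFrame(
                {
                    "marker_id": [f"{chrom}_m{i:06d}" for i in range(1, n + 1)],
                    "chrom": chrom,
                    "pos": pos,
                    "lrr": lrr,
                    "baf": baf,
                    "gc_fraction": gc,
                    "is_allelic": True,
                }
            )
        )
    track = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["marker_id", "chrom", "pos", "lrr", "baf", "gc_fraction", "is_allelic"]
    )
    return track, truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def gen_cohort(
    n_samples: int,
    effect: float,
    mutant_fraction: float,
    seed: int = 0,
    subtype_probs: dict[str, float] | None = None,
    platform: str = "rnaseq",
) -> pd.DataFrame:
    """Generate a cohort table of z-scores with a planted mutant-group shift.

    Wild-type z-scores are standard normal; the mutant group (exactly
    ``round(n_samples * mutant_fraction)`` samples) is shifted by ``effect``.
    Subtype labels are drawn from ``subtype_probs`` (default
    :data:`DEFAULT_SUBTYPE_PROBS`). Requires at least 2 samples per group.
    """
    if not 0 < mutant_fraction < 1:
        raise ValueError("mutant_fraction must be in (0, 1)")
    n_mutant = int(round(n_samples * mutant_fraction))
    n_wt = n_samples - n_mutant
    if min(n_mutant, n_wt) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got mutant={n_mutant}, wild-type={n_wt})"
        )
    probs = subtype_probs if subtype_probs is not None else DEFAULT_SUBTYPE_PROBS
    labels = list(probs)
    weights = np.array([probs[k] for k in labels], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("subtype probabilities must sum to 1")

    rng = np.random.default_rng(seed)
    status = np.array(["mutant"] * n_mutant + ["wild-type"] * n_wt)
    rng.shuffle(status)
    z = rng.normal(0.0, 1.0, size=n_samples)
    z[status == "mutant"] += effect
    subtype = rng.choice(labels, size=n_samples, p=weights)
    return pd.DataFrame(
        {
            "sample_id": [f"case{i:04d}" for i in range(1, n_samples + 1)],
            "zscore": z,
            "mutation_status": status,
            "subtype": subtype,
            "platform": platform,
        }
    )
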