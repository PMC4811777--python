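"""TSV readers/writers for the pipeline's file formats.

All tabular inputs and outputs are plain tab-separated text:

* expression matrix — first column the gene id, header row of sample ids;
* sample annotation — ``sample_id, condition, replicate_group``;
* centroid set — ``gene`` plus one column per subtype;
* gene map — ``source, target``;
* marker track — ``marker_id, chrom, pos, lrr, baf, gc_fraction, is_allelic``;
* cohort — ``sample_id, zscore, mutation_status, subtype, platform``;
* BED export of segments — 0-based half-open, name column = state.
"""

from __future__ import annotations


import pandas as pd

from gbmkit.cnv import MARKER_COLUMNS, segments_to_bed
from gbmkit.expression import ExpressionMatrix, SampleAnnotation

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_centroids",
    "read_gene_map",
    "read_marker_track",
    "write_marker_track",
    "read_cohort",
    "write_table",
    "write_bed",
]


def read_expression(path, scale: str = "raw") -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(frame, scale=scale)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_annotation(path, reference: str) -> SampleAnnotation:
    return SampleAnnotation(pd.read_csv(path, sep="\t", dtype=str), reference=reference)


def write_annotation(annotation: SampleAnnotation, path) -> None:
    annotation.frame.to_csv(path, sep="\t", index=False)


def read_centroids(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_map(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"source", "target"} <= set(frame.columns):
        raise ValueError("gene map TSV needs 'source' and 'target' columns")
    return frame


def read_marker_track(path) -> pd.DataFrame:
    track = pd.read_csv(
        path, sep="\t", dtype={"marker_id": str, "chrom": str}
    )
    missing = set(MARKER_COLUMNS[:4]) - set(track.columns)
    if missing:
        raise ValueError(f"marker track is missing columns: {sorted(missing)}")
    return track


def write_marker_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if not {"sample_id", "zscore"} <= set(table.columns):
        raise ValueError("cohort TSV needs 'sample_id' and 'zscore' columns")
    return table


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def write_bed(segments: pd.DataFrame, path) -> None:
    segments_to_bed(segments).to_csv(path, sep="\t", index=False, header=False)
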