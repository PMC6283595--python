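"""Text-format I/O: FASTA, BED, bedGraph, pairs tables, dense matrix TSV.

Every writer accepts an optional provenance header (version, seed, and the
full parameter set of the producing run) emitted as ``#`` comment lines;
every reader skips ``#`` and ``track`` lines.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .chic import PAIR_COLUMNS, ContactMatrix
from .locus import DomainAnnotation, FragmentMap, GenomicInterval

PathLike = Union[str, Path]

_DOMAIN_LABELS = {"cdom", "tdom", "next_tad", "cluster"}


def provenance_header(seed: Optional[int] = None, **params) -> list[str]:
    fields = {"program": "tadquant", "version": __version__}
    if seed is not None:
        fields["seed"] = seed
    fields.update(params)
    return [f"# {k}={v}" for k, v in fields.items()]


def _write_lines(path: PathLike, header: Sequence[str], lines: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for line in lines:
            fh.write(line + "\n")


def read_fasta(path: PathLike) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True, rebuild=False) as fasta:
        return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_fasta(path: PathLike, sequences: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def _data_lines(path: PathLike) -> Iterable[list[str]]:
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield line.split("\t")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    out = []
    for parts in _data_lines(path):
        name = parts[3] if len(parts) > 3 else None
        out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_bed(
    path: PathLike,
    intervals: Iterable[GenomicInterval],
    header: Sequence[str] = (),
) -> None:
    lines = (
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}" for iv in intervals
    )
    _write_lines(path, header, lines)


def read_annotation(path: PathLike, pad_bp: int = 10_000) -> DomainAnnotation:
    """Read a BED4 annotation; names cdom/tdom/next_tad/cluster are the
    domains (case-insensitive), all other named rows become named regions."""
    domains: dict[str, GenomicInterval] = {}
    named: dict[str, GenomicInterval] = {}
    for iv in read_bed(path):
        if iv.name is None:
            raise ValueError("annotation BED requires a name column")
        key = iv.name.lower().replace("-", "_")
        if key in _DOMAIN_LABELS:
            domains[key] = iv
        else:
            named[iv.name] = iv
    missing = {"cdom", "tdom", "cluster"} - set(domains)
    if missing:
        raise ValueError(f"annotation missing required labels: {sorted(missing)}")
    return DomainAnnotation(
        cdom=domains["cdom"],
        tdom=domains["tdom"],
        cluster=domains["cluster"],
        next_tad=domains.get("next_tad"),
        named_regions=named,
        pad_bp=pad_bp,
    )


def write_annotation(path: PathLike, annotation: DomainAnnotation,
                     header: Sequence[str] = ()) -> None:
    rows = [
        GenomicInterval(d.chrom, d.start, d.end, label)
        for label, d in {**annotation.domains(), "cluster": annotation.cluster}.items()
    ] + [
        GenomicInterval(r.chrom, r.start, r.end, label)
        for label, r in annotation.named_regions.items()
    ]
    write_bed(path, rows, header)


def write_fragment_map(path: PathLike, fm: FragmentMap,
                       header: Sequence[str] = ()) -> None:
    lines = (
        f"{f.chrom}\t{f.start}\t{f.end}\tfrag_{i}"
        for i, f in enumerate(fm.fragments)
    )
    _write_lines(path, header, lines)


def read_bedgraph_scores(path: PathLike, fm: FragmentMap) -> np.ndarray:
    """Per-fragment scores from a bedGraph keyed to a fragment map.

    Each bedGraph interval must match one fragment exactly; fragments
    without a row score 0.
    """
    index = {(f.chrom, f.start, f.end): i for i, f in enumerate(fm.fragments)}
    scores = np.zeros(len(fm))
    for parts in _data_lines(path):
        key = (parts[0], int(parts[1]), int(parts[2]))
        if key not in index:
            raise ValueError(f"bedGraph interval {key} not in fragment map")
        scores[index[key]] = float(parts[3])
    return scores


def write_bedgraph(
    path: PathLike,
    intervals: Iterable[GenomicInterval],
    values: Sequence[float],
    header: Sequence[str] = (),
) -> None:
    lines = (
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{val:.6g}"
        for iv, val in zip(intervals, values)
    )
    _write_lines(path, header, lines)


def read_pairs(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=PAIR_COLUMNS)
    return df.astype(
        {"pos1": np.int64, "pos2": np.int64, "mapq1": np.int64, "mapq2": np.int64}
    )


def write_pairs(path: PathLike, pairs: pd.DataFrame,
                header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        pairs[PAIR_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def write_matrix_tsv(path: PathLike, matrix: ContactMatrix,
                     which: str = "balanced", header: Sequence[str] = ()) -> None:
    """Dense matrix TSV with bin-start coordinates as row/column labels."""
    values = getattr(matrix, which)
    if values is None:
        raise ValueError(f"matrix has no {which} values")
    starts = [matrix.bin_start(i) for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=starts, columns=starts)
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", float_format="%.8g")


def read_matrix_tsv(path: PathLike, span: GenomicInterval, bin_size: int,
                    which: str = "balanced") -> ContactMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    values = frame.to_numpy(dtype=float)
    matrix = ContactMatrix(span=span, bin_size=bin_size)
    if which == "balanced":
        matrix.balanced = values
        matrix.bad_bins = np.isnan(values).all(axis=1)
    elif which == "counts":
        matrix.counts = values
    else:
        raise ValueError(f"unknown matrix kind {which!r}")
    return matrix


def write_json(path: PathLike, payload: dict, seed: Optional[int] = None,
               **params) -> None:
    doc = {"_provenance": {"program": "tadquant", "version": __version__}}
    if seed is not None:
        doc["_provenance"]["seed"] = seed
    doc["_provenance"].update(params)
    doc.update(payload)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
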