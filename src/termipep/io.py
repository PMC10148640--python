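"""File-format plumbing: gene catalogs, read sets, truth tables and result tables.

Catalogs travel as FASTA plus a sidecar TSV carrying the per-gene annotation
(category, peripheral flag, 3'-UTR length).  Read sets are (optionally
gzipped) FASTA whose headers are ``spot_id`` for single-end spots and
``spot_id/1`` / ``spot_id/2`` for paired spots.  Ground truth and manifests
are JSON.
"""

from __future__ import annotations

import gzip
import json
import os
from typing import TYPE_CHECKING

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .synth import Catalog, ReadSet


def _open_maybe_gz(path: str, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


# ---------------------------------------------------------------- catalogs

def write_catalog(catalog: "Catalog", fasta_path: str, tsv_path: str | None = None) -> None:
    """Write a catalog as FASTA plus a sidecar annotation TSV.

    When *tsv_path* is omitted the sidecar sits next to the FASTA with a
    ``.tsv`` extension.
    """
    if tsv_path is None:
        tsv_path = os.path.splitext(fasta_path)[0] + ".tsv"
    records = [
        SeqRecord(Seq(g.cds), id=g.gene_id, description=g.name) for g in catalog.genes
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in catalog.genes],
            "name": [g.name for g in catalog.genes],
            "category": [g.category for g in catalog.genes],
            "peripheral": [int(g.peripheral) for g in catalog.genes],
            "utr3_len": [g.utr3_len for g in catalog.genes],
        }
    ).to_csv(tsv_path, sep="\t", index=False)


def read_catalog(fasta_path: str, tsv_path: str | None = None) -> "Catalog":
    from .synth import Catalog, GeneRecord

    if tsv_path is None:
        tsv_path = os.path.splitext(fasta_path)[0] + ".tsv"
    meta = pd.read_csv(tsv_path, sep="\t").set_index("gene_id")
    genes = []
    with _open_maybe_gz(fasta_path, "r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            row = meta.loc[rec.id]
            genes.append(
                GeneRecord(
                    gene_id=rec.id,
                    name=str(row["name"]),
                    cds=str(rec.seq).upper(),
                    category=str(row["category"]),
                    peripheral=bool(row["peripheral"]),
                    utr3_len=int(row["utr3_len"]),
                )
            )
    return Catalog(genes)


# ---------------------------------------------------------------- read sets

def write_readset(readset: "ReadSet", path: str) -> None:
    """Write spots as FASTA(.gz); paired mates get ``/1`` and ``/2`` suffixes."""
    with _open_maybe_gz(path, "w") as fh:
        for spot_id, reads in readset.spots:
            if len(reads) == 1:
                fh.write(f">{spot_id}\n{reads[0]}\n")
            else:
                for i, r in enumerate(reads, start=1):
                    fh.write(f">{spot_id}/{i}\n{r}\n")


def read_readset(path: str, set_id: str | None = None,
                 labels: dict | None = None) -> "ReadSet":
    """Read a spot FASTA(.gz), re-grouping ``/1``/``/2`` mates into spots.

    Spot order follows first appearance in the file, which is what the
    first-N subsampled counting mode relies on.
    """
    from .synth import ReadSet

    if set_id is None:
        set_id = os.path.basename(path).split(".")[0]
    spots: dict[str, list[str]] = {}
    order: list[str] = []
    with _open_maybe_gz(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            sid = rec.id
            if sid.endswith("/1") or sid.endswith("/2"):
                sid = sid[:-2]
            if sid not in spots:
                spots[sid] = []
                order.append(sid)
            spots[sid].append(str(rec.seq).upper())
    return ReadSet(
        set_id=set_id,
        spots=[(sid, tuple(spots[sid])) for sid in order],
        labels=labels or {},
    )


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Read a sample sheet TSV mapping read-set files to labels.

    Expected columns: set_id plus any of path, species, caste, tissue
    (extra columns pass through untouched).
    """
    sheet = pd.read_csv(path, sep="\t")
    if "set_id" not in sheet.columns:
        raise ValueError("sample sheet missing column: set_id")
    return sheet


# ---------------------------------------------------------------- JSON / tables

def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")
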