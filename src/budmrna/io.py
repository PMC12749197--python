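"""Readers and writers for the package's text formats.

FASTA goes through Biopython; spot and detection tables are delimited text
(comma or tab, auto-detected) with a header.  Hit tables are written
tab-delimited, plus a BED-like track in 0-based half-open coordinates for
genome-browser use.  Transcript-internal coordinates are 1-based inclusive
with the A of ATG as +1.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .lineage import Detection
from .spatial import SPOT_COLUMNS
from .transcript import Transcript

DETECTION_COLUMNS = ["frame", "id", "kind", "x_px", "y_px", "area_px2", "nucleus_flag"]


def read_fasta(path, cds_bounds: dict[str, tuple[int, int]] | None = None) -> list[Transcript]:
    """Read (multi-)FASTA into transcripts, order preserved, upper-cased.

    ``cds_bounds`` maps record id -> (cds_start, cds_end); records without
    an entry default to a CDS covering the largest in-frame prefix.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id}: empty sequence")
        if cds_bounds and rec.id in cds_bounds:
            s, e = cds_bounds[rec.id]
        else:
            s, e = 1, len(seq) - len(seq) % 3
        out.append(Transcript(id=rec.id, seq=seq, cds_start=s, cds_end=e))
    return out


def write_fasta(transcripts: list[Transcript], path) -> None:
    records = [SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts]
    SeqIO.write(records, str(path), "fasta")


def read_cds_sidecar(path) -> dict[str, tuple[int, int]]:
    """Tab-delimited sidecar: id, cds_start, cds_end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "cds_start", "cds_end"])
    return {str(r.id): (int(r.cds_start), int(r.cds_end)) for r in df.itertuples()}


def _read_delimited(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_spots(path) -> pd.DataFrame:
    """Read a spot table (x_um, y_um, z_um, intensity, channel, cell_id, is_ts)."""
    df = _read_delimited(path, ["x_um", "y_um", "z_um", "intensity", "channel", "cell_id"])
    if "is_ts" not in df.columns:
        df["is_ts"] = False
    for col in ("x_um", "y_um", "z_um", "intensity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column {col}, row {int(bad[0])}")
        df[col] = vals
    df["is_ts"] = df["is_ts"].astype(bool)
    print(f"read {len(df)} spots from {path}", file=sys.stderr)
    return df[SPOT_COLUMNS + [c for c in df.columns if c not in SPOT_COLUMNS]]


def write_spots(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_detections(path) -> list[Detection]:
    df = _read_delimited(path, DETECTION_COLUMNS)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                Detection(
                    frame=int(row["frame"]),
                    id=int(row["id"]),
                    centroid=(float(row["x_px"]), float(row["y_px"])),
                    area=float(row["area_px2"]),
                    nucleus_flag=bool(row["nucleus_flag"]),
                    kind=str(row["kind"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad detection row {i}: {exc}") from exc
    print(f"read {len(out)} detections from {path}", file=sys.stderr)
    return out


def write_detections(detections: list[Detection], path) -> None:
    rows = [
        dict(
            frame=d.frame, id=d.id, kind=d.kind, x_px=d.centroid[0], y_px=d.centroid[1],
            area_px2=d.area, nucleus_flag=d.nucleus_flag,
        )
        for d in detections
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS[:2] + ["kind", "x_px", "y_px", "area_px2", "nucleus_flag"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# hit tables


def hits_to_table(transcript: Transcript, hits) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            dict(
                transcript=transcript.id,
                span_start=h.span[0],
                span_end=h.span[1],
                frame=h.frame,
                cds_start=h.cds_span[0] if h.cds_span else "",
                cds_end=h.cds_span[1] if h.cds_span else "",
                outer_stem=f"{h.candidate.outer.left_start}-{h.candidate.outer.left_end}/"
                f"{h.candidate.outer.right_start}-{h.candidate.outer.right_end}",
                inner_stem=f"{h.candidate.inner.left_start}-{h.candidate.inner.left_end}/"
                f"{h.candidate.inner.right_start}-{h.candidate.inner.right_end}",
                dG_free=h.fold_free.dG,
                dG_constrained=h.fold_constrained.dG,
                stem_in_mfe=h.stem_in_mfe,
                dG_ratio_ok=h.dG_ratio_ok,
                n_merged=h.n_merged,
            )
        )
    return pd.DataFrame(rows)


def write_hits(transcript: Transcript, hits, path, bed_path=None) -> None:
    hits_to_table(transcript, hits).to_csv(path, sep="\t", index=False)
    if bed_path:
        with open(bed_path, "w") as fh:
            for h in hits:
                # BED: 0-based half-open
                fh.write(f"{transcript.id}\t{h.span[0] - 1}\t{h.span[1]}\tzipcode\n")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_provenance(path, **record) -> None:
    """Record parameters, seed and engine versions next to every output."""
    try:
        import RNA

        record.setdefault("viennarna", RNA.__version__)
    except ImportError:
        pass
    import numpy, scipy

    record.setdefault("numpy", numpy.__version__)
    record.setdefault("scipy", scipy.__version__)
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
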