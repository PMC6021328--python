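"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: probe TSV (sample, chrom, pos, value), SEG dialect
(sample, chrom, start, end, num_probes, seg_mean — seg_mean in arbitrary
copy-number units, NOT log2 ratio, declared by a header comment), clinical
TSV, and amplicon report TSV.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .calling import Amplicon, ProbeTrack, Segment
from .genome import GenomicInterval, normalize_chrom

SEG_HEADER_COMMENT = "#seg_mean_units=arbitrary_copy_number (diploid=2, not log2 ratio)"
SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes", "seg_mean"]


def write_probe_tsv(tracks: Sequence[ProbeTrack], path) -> None:
    frames = [
        pd.DataFrame({"sample": t.sample, "chrom": t.chrom, "pos": t.pos,
                      "value": t.value})
        for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_probe_tsv(path) -> dict[str, ProbeTrack]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"sample", "chrom", "pos", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: probe TSV missing columns {sorted(missing)}")
    return {
        sample: ProbeTrack(sample, sub["chrom"], sub["pos"], sub["value"])
        for sample, sub in df.groupby("sample", sort=True)
    }


def write_seg(segments_by_sample: dict[str, Sequence[Segment]], path) -> None:
    with open(path, "w") as fh:
        fh.write(SEG_HEADER_COMMENT + "\n")
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for sample in segments_by_sample:
            for s in segments_by_sample[sample]:
                iv = s.interval
                fh.write(
                    f"{sample}\t{iv.chrom}\t{iv.start}\t{iv.end}"
                    f"\t{s.n_probes}\t{s.mean:.6g}\n"
                )


def read_seg(path) -> dict[str, list[Segment]]:
    """Read a SEG-dialect file; tolerates the unit-declaring comment header."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    rename = {}
    for col in df.columns:
        lc = col.lower().replace(".", "_")
        if lc in ("id", "sample_id"):
            rename[col] = "sample"
        elif lc in ("loc_start", "chromstart"):
            rename[col] = "start"
        elif lc in ("loc_end", "chromend"):
            rename[col] = "end"
        elif lc in ("num_mark", "n_probes"):
            rename[col] = "num_probes"
        elif lc == "chromosome":
            rename[col] = "chrom"
        elif lc in SEG_COLUMNS and lc != col:
            rename[col] = lc
    df = df.rename(columns=rename)
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: SEG file missing columns {sorted(missing)}")
    out: dict[str, list[Segment]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(Segment(
            GenomicInterval(normalize_chrom(str(row.chrom)),
                            int(row.start), int(row.end)),
            float(row.seg_mean), int(row.num_probes),
        ))
    return out


def write_amplicon_tsv(amplicons_by_sample: dict[str, Sequence[Amplicon]], path):
    rows = []
    roster = ",".join(amplicons_by_sample)
    for sample, amps in amplicons_by_sample.items():
        for a in amps:
            rows.append({
                "sample": sample,
                "chrom": a.interval.chrom,
                "start": a.interval.start,
                "end": a.interval.end,
                "mean": round(a.mean, 6),
                "n_probes": a.n_probes,
                "bands": ",".join(a.bands),
                "genes": ",".join(a.genes),
                "arms": ",".join(a.arms),
                "whole_chrom_suspect": a.whole_chrom_suspect,
            })
    cols = ["sample", "chrom", "start", "end", "mean", "n_probes",
            "bands", "genes", "arms", "whole_chrom_suspect"]
    with open(path, "w") as fh:
        # roster comment keeps zero-amplicon samples visible to readers
        fh.write(f"#samples={roster}\n")
        pd.DataFrame(rows, columns=cols).to_csv(fh, sep="\t", index=False)


def read_amplicon_tsv(path) -> dict[str, list[Amplicon]]:
    out: dict[str, list[Amplicon]] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#samples="):
        for sample in first.removeprefix("#samples=").strip().split(","):
            if sample:
                out[sample] = []
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str},
                     keep_default_na=False)
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(Amplicon(
            GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
            float(row.mean), int(row.n_probes),
            bands=tuple(b for b in str(row.bands).split(",") if b),
            genes=tuple(g for g in str(row.genes).split(",") if g),
            arms=tuple(a for a in str(row.arms).split(",") if a),
            whole_chrom_suspect=bool(row.whole_chrom_suspect in (True, "True")),
        ))
    return out


def read_clinical_tsv(path) -> pd.DataFrame:
    # explicit NA tokens only: "None" is a real chemotherapy category
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""],
                     keep_default_na=False, dtype={"id": str})
    required = {"id", "os_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical TSV missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"])
        raise ValueError(f"{path}: duplicate ids {dupes}")
    return df
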