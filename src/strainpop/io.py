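"""File-format adapters: VCF import/export and tabular result writers.

The canonical internal format is the counts TSV handled by
:class:`~strainpop.snv.AlleleCountMatrix`; VCF (with per-sample AD/DP or AF
and the GATK-style INFO annotations) is an import/export dialect.
Coordinates are 1-based inclusive within genes, matching VCF convention.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .snv import BASES, SNVRecord

_INFO_KEYS = ("QD", "FS", "MQ", "BaseQRMS", "MQRankSum", "ReadPosRankSum")


def write_vcf(
    records: Sequence[SNVRecord],
    path,
    samples: Sequence[str] | None = None,
    gene_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write SNV records to an uncompressed VCF with per-sample AF genotypes."""
    if samples is None:
        seen: dict = {}
        for r in records:
            for s in r.freqs:
                seen.setdefault(s, None)
        samples = list(seen)
    header = pysam.VariantHeader()
    contigs = {}
    for r in records:
        contigs[r.gene_id] = max(contigs.get(r.gene_id, 0), r.pos)
    for gid in sorted(contigs):
        length = (gene_lengths or {}).get(gid, contigs[gid])
        header.contigs.add(gid, length=length)
    for key in _INFO_KEYS:
        header.info.add(key, number=1, type="Float", description=f"{key} annotation")
    header.formats.add("AF", number=1, type="Float", description="Alternative allele frequency")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in sorted(records, key=lambda r: (r.gene_id, r.pos)):
            rec = vcf.new_record(
                contig=r.gene_id, start=r.pos - 1, stop=r.pos, alleles=(r.ref, *r.alts)
            )
            for key in _INFO_KEYS:
                val = r.annotations.get(key)
                if val is not None and not (isinstance(val, float) and np.isnan(val)):
                    rec.info[key] = float(val)
            for s in samples:
                f = r.freqs.get(s)
                if f is not None and not (isinstance(f, float) and np.isnan(f)):
                    rec.samples[s]["AF"] = float(f)
            vcf.write(rec)


def read_vcf(path) -> list[SNVRecord]:
    """Read SNV records from VCF; alt frequencies from AF or AD/DP fields."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            annotations = {}
            for key in _INFO_KEYS:
                if key in rec.info:
                    annotations[key] = float(rec.info[key])
            freqs = {}
            for s in samples:
                fmt = rec.samples[s]
                if "AF" in fmt and fmt.get("AF") is not None:
                    freqs[s] = float(fmt["AF"])
                elif "AD" in fmt and fmt.get("AD") is not None:
                    ad = fmt["AD"]
                    dp = sum(x for x in ad if x is not None)
                    freqs[s] = float(sum(ad[1:]) / dp) if dp else float("nan")
                else:
                    freqs[s] = float("nan")
            out.append(
                SNVRecord(
                    gene_id=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=alts,
                    freqs=freqs,
                    annotations=annotations,
                )
            )
    return out


def write_table(df: pd.DataFrame, path, statistic: str, params: Mapping, index_label=None) -> None:
    """Write a result table with a header naming statistic, parameters and seed."""
    meta = " ".join(f"{k}={v}" for k, v in params.items())
    with open(path, "w") as fh:
        fh.write(f"# statistic={statistic} {meta}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def read_frequencies_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("sample")
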