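"""Writers for heteroplasmy calls: VCF (via pysam) and flat TSV mirror."""

from __future__ import annotations

import pandas as pd
import pysam

from .reference import MT_LENGTH


def write_calls_vcf(calls: pd.DataFrame, path, sample_id: str | None = None,
                    contig: str = "chrM") -> None:
    """One VCF record per heteroplasmy: VAF in AF, depth in DP, the
    log-likelihood quality score in LLQ, strand-test P in SP."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={MT_LENGTH}>")
    header.add_meta("INFO", items=[("ID", "AF"), ("Number", "A"),
                                   ("Type", "Float"),
                                   ("Description", "Minor allele fraction")])
    header.add_meta("INFO", items=[("ID", "DP"), ("Number", "1"),
                                   ("Type", "Integer"),
                                   ("Description", "Unique read depth")])
    header.add_meta("INFO", items=[("ID", "LLQ"), ("Number", "1"),
                                   ("Type", "Float"),
                                   ("Description",
                                    "BAQ-based log-likelihood quality")])
    header.add_meta("INFO", items=[("ID", "SP"), ("Number", "1"),
                                   ("Type", "Float"),
                                   ("Description",
                                    "Strand concordance exact P")])
    header.add_meta("INFO", items=[("ID", "SECONDARY"), ("Number", "0"),
                                   ("Type", "Flag"),
                                   ("Description",
                                    "Rescued by the sharing test")])
    sample = sample_id or (calls.sample_id.iloc[0]
                           if len(calls) and "sample_id" in calls else "NA")
    header.add_sample(str(sample))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in calls.itertuples():
            rec = vcf.new_record(contig=contig, start=int(c.pos) - 1,
                                 stop=int(c.pos), alleles=(c.ref, c.alt))
            rec.info["AF"] = float(c.vaf)
            rec.info["DP"] = int(c.depth)
            rec.info["LLQ"] = float(c.llq)
            rec.info["SP"] = float(c.strand_p)
            if getattr(c, "secondary", False):
                rec.info["SECONDARY"] = True
            vcf.write(rec)


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path) -> pd.DataFrame:
    """Pileup TSV with documented columns (pos, ref, strand-split allele
    counts, per-allele mean BAQ, frac_baq30)."""
    return pd.read_csv(path, sep="\t")
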