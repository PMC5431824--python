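"""VCF reading (cyvcf2) and deterministic VCF v4.2 writing.

Dosage is always the ALT-allele count of a diploid GT call: 0, 1, 2, or
missing for ``./.`` and half-calls. Multi-allelic records are skipped with a
logged count. Positions are 1-based throughout, as in VCF itself.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ParseError
from .types import GenotypeMatrix

log = logging.getLogger(__name__)


def read_vcf(path: str) -> GenotypeMatrix:
    """Parse a VCF v4.x with a GT field into a :class:`GenotypeMatrix`.

    ``./.`` and half-calls become missing; records with more than one ALT
    allele are skipped (count logged).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:
        raise ParseError(f"cannot open {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: no samples in VCF header")

    rows, meta = [], []
    n_multi = 0
    for i, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.genotypes
        if gts is None:
            raise ParseError(f"{path}: record {i} ({rec.CHROM}:{rec.POS}) "
                             "has no GT field")
        dos = np.empty(len(samples))
        for k, g in enumerate(gts):
            a, b = g[0], g[1] if len(g) > 2 else -1
            dos[k] = np.nan if (a < 0 or b < 0) else float(a + b)
        rows.append(dos)
        meta.append((rec.CHROM, rec.POS,
                     rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}",
                     rec.REF, rec.ALT[0]))
    vcf.close()
    if n_multi:
        log.info("skipped %d multi-allelic record(s) in %s", n_multi, path)
    if not meta:
        dosages = np.empty((len(samples), 0))
    else:
        dosages = np.vstack(rows).T
    snps = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeMatrix(dosages=dosages, snps=snps, samples=samples)


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a deterministic VCF v4.2: contigs declared, records ordered by
    (chrom, pos), diploid GT field, ``./.`` for missing calls."""
    order = G.snps.sort_values(["chrom", "pos"], kind="mergesort").index
    gt_text = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    lines = ["##fileformat=VCFv4.2",
             "##source=dioecy",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for contig in pd.unique(G.snps.loc[order, "chrom"]):
        lines.append(f"##contig=<ID={contig}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in G.samples))
    for j in order:
        row = G.snps.loc[j]
        calls = [gt_text.get(v, "./.") if not np.isnan(v) else "./."
                 for v in G.dosages[:, j]]
        lines.append("\t".join([
            str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
            str(row["ref"]), str(row["alt"]), ".", "PASS", ".", "GT",
            *calls]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
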