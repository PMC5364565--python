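"""Reading and writing genotype tables (TSV and VCF) and truth files.

The native genotype TSV is one row per marker::

    #parent1=<mother id>
    #parent2=<father id>
    marker_id  chromosome  position_cM  informativeness  parent1_gt  parent2_gt  <off1> ...
    m0001      chr15       54.6         maternal         AB          AA          AB ...
    ...
    sex        -           -            -                -           -           F ...

with genotype codes AA/AB/BB/-- (allele A = reference parent allele) and a
trailing ``sex`` pseudo-row of F/M/U phenotype labels.

VCF v4.2 export writes one sample per offspring plus the two parents (GT
only), the cM position in INFO key ``CM`` and the informativeness class in
INFO key ``INF``; sex goes to a sidecar TSV of (id, sex).  VCF handling is
delegated to pysam.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import CODE_TO_STR, MISSING, STR_TO_CODE, GenotypeTable
from .markers import MarkerMap
from .pedigree import TruthSet

__all__ = [
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_vcf",
    "read_vcf",
    "write_sex_tsv",
    "read_sex_tsv",
    "write_truth_tsv",
]


def write_genotype_tsv(table: GenotypeTable, path) -> None:
    mm = table.markers.df
    with open(path, "w") as fh:
        fh.write(f"#parent1={table.mother_id}\n#parent2={table.father_id}\n")
        off = list(table.offspring_ids)
        fh.write("\t".join(["marker_id", "chromosome", "position_cM", "informativeness",
                            "parent1_gt", "parent2_gt"] + off) + "\n")
        for mid in table.markers.marker_ids:
            row = [mid, str(mm.loc[mid, "chromosome"]),
                   repr(float(mm.loc[mid, "position_cM"])), str(mm.loc[mid, "informativeness"]),
                   CODE_TO_STR[int(table.parents.loc[mid, "mother"])],
                   CODE_TO_STR[int(table.parents.loc[mid, "father"])]]
            row += [CODE_TO_STR[int(c)] for c in table.calls.loc[mid]]
            fh.write("\t".join(row) + "\n")
        fh.write("\t".join(["sex", "-", "-", "-", "-", "-"] +
                           [str(s) for s in table.sex]) + "\n")


def read_genotype_tsv(path) -> GenotypeTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    meta = {}
    body = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln[1:].partition("=")
            meta[key] = val
        else:
            body.append(ln.split("\t"))
    header, rows = body[0], body[1:]
    off = header[6:]
    sex_rows = [r for r in rows if r[0] == "sex"]
    marker_rows = [r for r in rows if r[0] != "sex"]

    mm = pd.DataFrame(
        {
            "chromosome": [r[1] for r in marker_rows],
            "position_cM": [float(r[2]) for r in marker_rows],
            "informativeness": [r[3] for r in marker_rows],
        },
        index=pd.Index([r[0] for r in marker_rows], name="marker_id"),
    )
    calls = pd.DataFrame(
        [[STR_TO_CODE[g] for g in r[6:]] for r in marker_rows],
        index=mm.index, columns=pd.Index(off, name="offspring_id"), dtype=np.int8,
    )
    parents = pd.DataFrame(
        {
            "mother": [STR_TO_CODE[r[4]] for r in marker_rows],
            "father": [STR_TO_CODE[r[5]] for r in marker_rows],
        },
        index=mm.index, dtype=np.int8,
    )
    sex = pd.Series(sex_rows[0][6:] if sex_rows else ["U"] * len(off),
                    index=calls.columns, name="sex")
    return GenotypeTable(markers=MarkerMap(mm), calls=calls, parents=parents, sex=sex,
                         mother_id=meta.get("parent1", "mother"),
                         father_id=meta.get("parent2", "father"))


def write_sex_tsv(sex: pd.Series, path) -> None:
    sex.rename("sex").rename_axis("id").to_csv(path, sep="\t")


def read_sex_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df["sex"]


_GT_FROM_CODE = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def _pos_from_cM(cm: float) -> int:
    # synthetic 1-based coordinate: 10 kb per cM keeps marker order
    return int(round(cm * 1e4)) + 1


def write_vcf(table: GenotypeTable, path, sex_path=None) -> None:
    import pysam

    mm = table.markers.df
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=CM,Number=1,Type=Float,Description="Map position in cM">')
    header.add_line('##INFO=<ID=INF,Number=1,Type=String,Description="Parental informativeness class">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in table.markers.chromosomes:
        max_pos = _pos_from_cM(float(mm.loc[mm["chromosome"] == chrom, "position_cM"].max()))
        header.contigs.add(chrom, length=max_pos + 1000)
    samples = [table.mother_id, table.father_id] + list(table.offspring_ids)
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for mid in table.markers.marker_ids:
            rec = vcf.new_record(
                contig=str(mm.loc[mid, "chromosome"]),
                start=_pos_from_cM(float(mm.loc[mid, "position_cM"])) - 1,
                alleles=("A", "T"),
                id=str(mid),
            )
            rec.info["CM"] = float(mm.loc[mid, "position_cM"])
            rec.info["INF"] = str(mm.loc[mid, "informativeness"])
            codes = [int(table.parents.loc[mid, "mother"]),
                     int(table.parents.loc[mid, "father"])]
            codes += [int(c) for c in table.calls.loc[mid]]
            for sample, code in zip(samples, codes):
                rec.samples[sample]["GT"] = _GT_FROM_CODE[code]
            vcf.write(rec)
    if sex_path is not None:
        write_sex_tsv(table.sex, sex_path)


def read_vcf(path, sex_path=None, mother_id=None, father_id=None) -> GenotypeTable:
    """Import a genotype table from a GT-only VCF written by :func:`write_vcf`.

    The first two samples are taken as mother and father unless ids are
    given explicitly.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        mother_id = mother_id or samples[0]
        father_id = father_id or samples[1]
        off = [s for s in samples if s not in (mother_id, father_id)]
        ids, chroms, cms, infs = [], [], [], []
        parent_codes, call_codes = [], []
        for rec in vcf:
            ids.append(rec.id)
            chroms.append(rec.contig)
            cms.append(float(rec.info.get("CM", rec.pos / 1e4)))
            infs.append(str(rec.info.get("INF", "uninformative")))

            def code(sample):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    return MISSING
                return int(sum(gt))

            parent_codes.append((code(mother_id), code(father_id)))
            call_codes.append([code(s) for s in off])

    index = pd.Index(ids, name="marker_id")
    mm = MarkerMap(pd.DataFrame({"chromosome": chroms, "position_cM": cms,
                                 "informativeness": infs}, index=index))
    calls = pd.DataFrame(call_codes, index=index,
                         columns=pd.Index(off, name="offspring_id"), dtype=np.int8)
    parents = pd.DataFrame(parent_codes, index=index,
                           columns=["mother", "father"], dtype=np.int8)
    sex = read_sex_tsv(sex_path).reindex(calls.columns).fillna("U") if sex_path \
        else pd.Series("U", index=calls.columns, name="sex")
    sex = sex.rename("sex")
    return GenotypeTable(markers=mm, calls=calls, parents=parents, sex=sex,
                         mother_id=mother_id, father_id=father_id)


def write_truth_tsv(truth: TruthSet, path) -> None:
    """Ground-truth inheritance as one row per offspring."""
    mat_names, pat_names = truth.maternal_label_names, truth.paternal_label_names
    with open(path, "w") as fh:
        fh.write("offspring_id\tsex\tviable\tsd_maternal\tsr_maternal\tsr_paternal"
                 "\tmaternal_labels\tpaternal_labels"
                 "\tmaternal_breakpoints\tpaternal_breakpoints\n")
        for oid in truth.sex.index:
            mlab = "".join(str(int(x)) for x in truth.maternal_labels.loc[oid])
            plab = "".join(str(int(x)) for x in truth.paternal_labels.loc[oid])
            mbp = ";".join(f"{a}-{b}" for a, b in truth.maternal_breakpoints[oid]) or "-"
            pbp = ";".join(f"{a}-{b}" for a, b in truth.paternal_breakpoints[oid]) or "-"
            fh.write("\t".join([
                str(oid), str(truth.sex.loc[oid]), str(bool(truth.viable.loc[oid])),
                str(truth.sd_maternal_label.loc[oid]),
                str(truth.sr_labels.loc[oid, "maternal"]),
                str(truth.sr_labels.loc[oid, "paternal"]),
                mlab, plab, mbp, pbp,
            ]) + "\n")
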