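"""Readers and writers for the pipeline's file formats.

Formats: HapMap text and VCF for genotypes, long-format TSV for replicated
phenotypes, TSV for trait matrices / association results / QTL reports /
co-location pairs, BED for region export (0-based half-open conversion),
GFF3 or TSV for gene annotations, JSON for truth sets, DOT + TSV for DAGs.

All writers emit a provenance comment line (tool version, seed, parameter
hash); readers skip ``#`` comment lines.  Internal coordinates stay 1-based
inclusive; only the BED export converts (start-1, end).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from panelqtl import __version__
from panelqtl.bn import Blacklist, Dag
from panelqtl.gwas import AssocRecord, assoc_frame
from panelqtl.phenostats import TraitMatrix
from panelqtl.regions import ColocPair, GeneAnnotation, QtlRegion
from panelqtl.simulate import GenotypeMatrix, PHENO_COLUMNS

__all__ = [
    "provenance_line",
    "read_hapmap", "write_hapmap",
    "read_vcf", "write_vcf",
    "read_phenotypes", "write_phenotypes",
    "read_subpops", "write_subpops",
    "read_trait_matrix", "write_trait_matrix",
    "read_assoc", "write_assoc",
    "write_qtl_report", "write_coloc",
    "read_gff3", "read_gene_table",
    "write_dag_dot", "write_dag_tsv", "write_blacklist",
]

_HAPMAP_HEADER = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
    "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def provenance_line(seed: int | None = None, params: dict | None = None) -> str:
    digest = ""
    if params is not None:
        blob = json.dumps(params, sort_keys=True, default=str).encode()
        digest = hashlib.sha256(blob).hexdigest()[:12]
    parts = [f"# panelqtl v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if digest:
        parts.append(f"params={digest}")
    return " ".join(parts)


def _write_with_header(df: pd.DataFrame, path, header_lines: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes: HapMap

def write_hapmap(G: GenotypeMatrix, path, seed: int | None = None) -> None:
    cols = _HAPMAP_HEADER + list(G.accessions)
    rows = []
    for j in range(G.n_snps):
        ref = str(G.snp_map.at[j, "ref"])
        alt = str(G.snp_map.at[j, "alt"])
        geno = []
        for d in G.dosages[:, j]:
            if np.isnan(d):
                geno.append("NN")
            elif d == 0:
                geno.append(ref + ref)
            elif d == 2:
                geno.append(alt + alt)
            else:
                geno.append(ref + alt)
        rows.append([
            str(G.snp_map.at[j, "snp"]), f"{ref}/{alt}",
            str(G.snp_map.at[j, "chrom"]), int(G.snp_map.at[j, "pos"]),
            "+", "NA", "NA", "NA", "NA", "NA", "NA", *geno,
        ])
    df = pd.DataFrame(rows, columns=cols)
    _write_with_header(df, path, [provenance_line(seed)])


def read_hapmap(path, inbred_strict: bool = True) -> GenotypeMatrix:
    """Parse a tab-delimited HapMap genotype file.

    Dosage counts copies of the non-reference allele.  Heterozygote codes
    under ``inbred_strict`` raise a warning and become missing; unresolvable
    codes become missing.
    """
    # leading full-line comments only: '#' also appears inside the rs# header
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str)
    got = [c.strip() for c in df.columns[:11]]
    if got[:4] != ["rs#", "alleles", "chrom", "pos"]:
        raise ValueError(
            f"malformed HapMap header at line {skip + 1}: "
            f"expected rs#/alleles/chrom/pos, got {got[:4]}"
        )
    accessions = list(df.columns[11:])
    snps, chroms, positions, refs, alts, dosage_cols = [], [], [], [], [], []
    n_het = 0
    for _, row in df.iterrows():
        alleles = str(row["alleles"]).split("/")
        if len(alleles) != 2:
            continue  # not biallelic
        ref, alt = alleles
        dos = np.full(len(accessions), np.nan)
        for i, acc in enumerate(accessions):
            code = str(row[acc])
            if len(code) != 2 or "N" in code:
                continue
            a, b = code[0], code[1]
            if a == ref and b == ref:
                dos[i] = 0.0
            elif a == alt and b == alt:
                dos[i] = 2.0
            elif {a, b} == {ref, alt}:
                if inbred_strict:
                    n_het += 1
                else:
                    dos[i] = 1.0
        snps.append(str(row["rs#"]))
        chroms.append(str(row["chrom"]))
        positions.append(int(row["pos"]))
        refs.append(ref)
        alts.append(alt)
        dosage_cols.append(dos)
    if n_het:
        warnings.warn(f"{n_het} heterozygote call(s) set to missing under inbred-strict mode")
    snp_map = pd.DataFrame({"snp": snps, "chrom": chroms, "pos": positions,
                            "ref": refs, "alt": alts})
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.zeros((len(accessions), 0))
    return GenotypeMatrix(dosages, snp_map, accessions, [""] * len(accessions),
                          inbred=inbred_strict)


# ---------------------------------------------------------------------------
# genotypes: VCF

def write_vcf(G: GenotypeMatrix, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=panelqtl_v{__version__}" + (f"_seed{seed}" if seed is not None else "") + "\n")
        for chrom in dict.fromkeys(G.snp_map["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.accessions) + "\n")
        for j in range(G.n_snps):
            gts = []
            for d in G.dosages[:, j]:
                if np.isnan(d):
                    gts.append("./.")
                elif d == 0:
                    gts.append("0/0")
                elif d == 2:
                    gts.append("1/1")
                else:
                    gts.append("0/1")
            fh.write("\t".join([
                str(G.snp_map.at[j, "chrom"]), str(int(G.snp_map.at[j, "pos"])),
                str(G.snp_map.at[j, "snp"]), str(G.snp_map.at[j, "ref"]),
                str(G.snp_map.at[j, "alt"]), ".", ".", ".", "GT", *gts,
            ]) + "\n")


def read_vcf(path, inbred_strict: bool = True) -> GenotypeMatrix:
    """Parse VCF genotypes: 0/0 -> 0, 1/1 -> 2, 0/1 -> 1 (missing under
    inbred-strict, with a warning), ./. -> missing.  Multi-allelic records
    are skipped with a reported count."""
    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    snps, chroms, positions, refs, alts, cols = [], [], [], [], [], []
    n_multi = 0
    n_het = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if "GT" not in (var.FORMAT or []):
            raise ValueError(f"record {var.CHROM}:{var.POS} lacks a GT field")
        dos = np.full(len(accessions), np.nan)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            total = a + b
            if total == 1:
                if inbred_strict:
                    n_het += 1
                    continue
                dos[i] = 1.0
            else:
                dos[i] = float(total)
        snps.append(var.ID if var.ID else f"S{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        positions.append(int(var.POS))
        refs.append(var.REF)
        alts.append(var.ALT[0])
        cols.append(dos)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic record(s)")
    if n_het:
        warnings.warn(f"{n_het} heterozygote call(s) set to missing under inbred-strict mode")
    snp_map = pd.DataFrame({"snp": snps, "chrom": chroms, "pos": positions,
                            "ref": refs, "alt": alts})
    dosages = np.column_stack(cols) if cols else np.zeros((len(accessions), 0))
    return GenotypeMatrix(dosages, snp_map, accessions, [""] * len(accessions),
                          inbred=inbred_strict)


# ---------------------------------------------------------------------------
# phenotypes / subpopulations / trait matrices

def write_phenotypes(records: pd.DataFrame, path, seed: int | None = None) -> None:
    _write_with_header(records[PHENO_COLUMNS], path, [provenance_line(seed)])


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns: {missing}")
    return df[PHENO_COLUMNS]


def write_subpops(labels: dict[str, str], path) -> None:
    df = pd.DataFrame({"accession": list(labels), "subpop": list(labels.values())})
    _write_with_header(df, path, [provenance_line()])


def read_subpops(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["accession"].astype(str), df["subpop"].astype(str)))


def write_trait_matrix(tm: TraitMatrix, path, seed: int | None = None) -> None:
    meta = {"kind": tm.kind, "transforms": tm.transforms}
    header = [provenance_line(seed), "# meta: " + json.dumps(meta, sort_keys=True)]
    df = tm.values.reset_index().rename(columns={"index": "accession"})
    df = df.rename(columns={df.columns[0]: "accession"})
    _write_with_header(df, path, header)


def read_trait_matrix(path) -> TraitMatrix:
    meta = {"kind": "blup", "transforms": {}}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta: "):
                meta = json.loads(line[len("# meta: "):])
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    values = df.set_index("accession")
    return TraitMatrix(values=values, transforms=dict(meta["transforms"]), kind=meta["kind"])


# ---------------------------------------------------------------------------
# association results

def write_assoc(records: list[AssocRecord], path, seed: int | None = None) -> None:
    _write_with_header(assoc_frame(records), path, [provenance_line(seed)])


def read_assoc(path) -> list[AssocRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        out.append(AssocRecord(
            snp=str(row["snp"]), chrom=str(row["chrom"]), pos=int(row["pos"]),
            minus_log10_p=float(row["minus_log10_p"]),
            effect_common=float(row["effect_common"]),
            common_allele=str(row["common_allele"]), alt_allele=str(row["alt_allele"]),
            n_common=int(row["n_common"]), n_alt=int(row["n_alt"]),
            pct_alt=float(row["pct_alt"]),
            trait=str(row.get("trait", "")), panel=str(row.get("panel", "")),
        ))
    return out


# ---------------------------------------------------------------------------
# QTL report / BED / co-location

def qtl_frame(qtls: list[QtlRegion], overlaps: dict[str, list[str]] | None = None) -> pd.DataFrame:
    rows = []
    overlaps = overlaps or {}
    for q in qtls:
        peak = q.peak
        rows.append({
            "qtl": q.name, "trait": q.trait, "chrom": q.chromosome,
            "start": q.start, "end": q.end, "size_mb": q.size_mb,
            "peak_pos": peak.pos, "panel": peak.panel,
            "minus_log10_p": peak.minus_log10_p,
            "effect_common": peak.effect_common,
            "common_allele": peak.common_allele, "alt_allele": peak.alt_allele,
            "n_common": peak.n_common, "n_alt": peak.n_alt,
            "pct_alt": peak.pct_alt,
            "overlaps": ",".join(overlaps.get(q.name, [])),
        })
    return pd.DataFrame(rows, columns=[
        "qtl", "trait", "chrom", "start", "end", "size_mb", "peak_pos",
        "panel", "minus_log10_p", "effect_common", "common_allele",
        "alt_allele", "n_common", "n_alt", "pct_alt", "overlaps",
    ])


def write_qtl_report(
    qtls: list[QtlRegion],
    colocs: list[ColocPair],
    path,
    bed_path=None,
    seed: int | None = None,
) -> None:
    """TSV mirroring the report column order plus a BED companion
    (0-based half-open: start-1, end)."""
    overlaps: dict[str, list[str]] = {}
    for pair in colocs:
        overlaps.setdefault(pair.qtl_a.name, []).append(pair.qtl_b.trait)
        overlaps.setdefault(pair.qtl_b.name, []).append(pair.qtl_a.trait)
    overlaps = {k: sorted(set(v)) for k, v in overlaps.items()}
    df = qtl_frame(qtls, overlaps)
    _write_with_header(df, path, [provenance_line(seed)])
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for q in qtls:
                fh.write(f"{q.chromosome}\t{q.start - 1}\t{q.end}\t{q.name}\n")


def write_coloc(colocs: list[ColocPair], path, seed: int | None = None) -> None:
    rows = [{
        "qtl_a": c.qtl_a.name, "trait_a": c.qtl_a.trait,
        "qtl_b": c.qtl_b.name, "trait_b": c.qtl_b.trait,
        "basis": c.basis, "gap": c.gap,
    } for c in colocs]
    df = pd.DataFrame(rows, columns=["qtl_a", "trait_a", "qtl_b", "trait_b", "basis", "gap"])
    _write_with_header(df, path, [provenance_line(seed)])


# ---------------------------------------------------------------------------
# gene annotations

def _normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.lstrip("0") or c


def read_gff3(path) -> list[GeneAnnotation]:
    """Gene features from a GFF3 file (type == gene); ID/Name and
    description/Note attributes populate the annotation."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("Name", f"{parts[0]}:{parts[3]}"))
            desc = attrs.get("description", attrs.get("Note", ""))
            genes.append(GeneAnnotation(
                gene_id=gene_id, chromosome=_normalize_chrom(parts[0]),
                start=int(parts[3]), end=int(parts[4]), description=desc,
            ))
    return genes


def read_gene_table(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GeneAnnotation(
            gene_id=str(r["gene_id"]), chromosome=_normalize_chrom(r["chrom"]),
            start=int(r["start"]), end=int(r["end"]),
            description=str(r.get("description", "")),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# DAG export

def write_dag_dot(dag: Dag, path) -> None:
    with open(path, "w") as fh:
        fh.write("digraph traits {\n")
        for node in dag.nodes:
            fh.write(f'  "{node}";\n')
        for (u, v), attrs in sorted(dag.arcs.items()):
            pen = 0.5 + 3.0 * attrs.get("strength", 1.0)
            fh.write(
                f'  "{u}" -> "{v}" [penwidth={pen:.2f}, '
                f'label="{attrs.get("coefficient", 0.0):.2f}"];\n'
            )
        fh.write("}\n")


def write_dag_tsv(dag: Dag, path, seed: int | None = None) -> None:
    rows = [{
        "from": u, "to": v,
        "strength": attrs.get("strength", 1.0),
        "coefficient": attrs.get("coefficient", float("nan")),
    } for (u, v), attrs in sorted(dag.arcs.items())]
    df = pd.DataFrame(rows, columns=["from", "to", "strength", "coefficient"])
    _write_with_header(df, path, [provenance_line(seed)])


def write_blacklist(bl: Blacklist, path) -> None:
    rows = [{"from": u, "to": v, "reason": reason}
            for (u, v), reason in sorted(bl.arcs.items())]
    df = pd.DataFrame(rows, columns=["from", "to", "reason"])
    _write_with_header(df, path, [provenance_line()])
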