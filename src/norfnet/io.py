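"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as TSV (ORFs x samples), genomic annotations as GFF3, interval
tracks as 6-column BED, ontologies as OBO + GAF. Coordinates are 0-based
half-open in memory and converted at the GFF3 boundary (1-based closed on
disk).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

ANNOTATION_COLUMNS = [
    "orf_id", "chrom", "start", "end", "strand", "orf_class",
    "conservation_label", "translation_evidence",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    """Write an ORF x sample integer count table (index = orf_id)."""
    counts.to_csv(path, sep="\t", index_label="orf_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="orf_id")


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Write ORF annotations as GFF3 (converts to 1-based closed starts)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            attrs = (
                f"ID={row.orf_id};orf_class={row.orf_class};"
                f"conservation={row.conservation_label};"
                f"translation_evidence={int(bool(row.translation_evidence))}"
            )
            fh.write(
                f"{row.chrom}\tnorfnet\tORF\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read ORF annotations written by :func:`write_gff3` (or any GFF3 whose
    attributes carry ID / orf_class / conservation keys)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append({
                "orf_id": attrs.get("ID"),
                "chrom": f[0],
                "start": int(f[3]) - 1,
                "end": int(f[4]),
                "strand": f[6],
                "orf_class": attrs.get("orf_class", "canonical"),
                "conservation_label": attrs.get("conservation", "other"),
                "translation_evidence": attrs.get("translation_evidence", "1") == "1",
            })
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_bed(track: pd.DataFrame, path) -> None:
    track.loc[:, BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS)
    df = df.iloc[:, :6]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col in BED_COLUMNS:
        if col not in df:
            df[col] = "." if col != "score" else 0
    return df


def write_obo(terms: dict, path) -> None:
    """Write a minimal OBO file.

    ``terms`` maps term id -> ``{"name": str, "is_a": [parent ids]}``.
    """
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: norfnet-sim\n")
        for tid, info in terms.items():
            fh.write(f"\n[Term]\nid: {tid}\nname: {info['name']}\n")
            fh.write("namespace: biological_process\n")
            for parent in info.get("is_a", []):
                fh.write(f"is_a: {parent}\n")


def write_gaf(term_to_genes: dict, path, taxon: str = "taxon:559292") -> None:
    """Write direct term -> gene annotations in GAF 2.2 layout."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for term, genes in term_to_genes.items():
            for gene in sorted(genes):
                cols = [
                    "NORFNET", gene, gene, "", term, "SIM:0000001", "IDA", "",
                    "P", gene, "", "gene", taxon, "20240101", "NORFNET", "", "",
                ]
                fh.write("\t".join(cols) + "\n")


def read_gaf(path) -> dict:
    """Read a GAF into a mapping term -> set of gene ids (ND evidence skipped)."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) > 6 and f[6] == "ND":
                continue
            out.setdefault(f[4], set()).add(f[1])
    return out


def read_term_gene_tsv(path) -> dict:
    """Read a two-column term<TAB>gene table into term -> gene set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"])
    return {t: set(g) for t, g in df.groupby("term")["gene"]}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
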