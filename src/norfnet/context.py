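"""Genomic context of de novo ORFs: conservation classification, orientation
relative to the nearest conserved neighbor, TSS inference from transcript
isoforms, promoter-sharing and terminator-interruption calls, TF-promoter
binding, and the piggybacking analysis combining them with expression,
coexpression and functional similarity.

Coordinates are 0-based half-open throughout; the gap between two ORFs is
``start2 - end1`` and "within 500 bp" means gap <= 500. Upstream/downstream
is always judged in the conserved neighbor's transcription direction, so
``up_opposite`` pairs are divergent and ``down_opposite`` convergent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import cliffs_delta, mann_whitney

__all__ = [
    "OrientationRecord", "classify_conservation", "classify_orientation",
    "tss_from_tifs", "promoter_tf_binding", "shared_promoter",
    "shared_transcript_fraction", "terminator_between", "piggyback_analysis",
    "CAN_PIGGYBACK",
]

CATEGORIES = ["down_same", "up_same", "up_opposite", "down_opposite",
              "antisense_overlap", "independent", "ambiguous"]
CAN_PIGGYBACK = {"up_opposite", "up_same", "down_same"}


# ---------------------------------------------------------------------------
# conservation

def classify_conservation(orfs: pd.DataFrame, rfc: pd.DataFrame,
                          hits: pd.DataFrame, e_cut: float = 1e-4,
                          rfc_denovo: float = 0.6, rfc_cons: float = 0.8
                          ) -> pd.Series:
    """Label each ORF conserved / de_novo / other from homology evidence.

    ``rfc`` columns: orf_id, distant RFC values (columns starting with
    ``rfc_``, the two most distant branches being ``rfc_distant1/2``) and
    ``mean_rfc``. ``hits`` columns: orf_id, search ('tblastn' | 'blastp' |
    'self_blastp'), evalue, outside_genus (bool; for self_blastp the flag
    marks a hit to a canonical ORF).

    Conserved: mean RFC > ``rfc_cons`` or any tblastn/blastp hit outside
    the genus below ``e_cut``. De novo: translated, no outside-genus hit,
    no self-blastp hit to a canonical ORF, not same-strand overlapping a
    canonical ORF, and both most-distant-branch RFCs < ``rfc_denovo``.
    Candidates lacking RFC rows are labeled other with a warning.
    """
    ann = orfs.set_index("orf_id")
    rfc_t = rfc.set_index("orf_id")
    out_hits: dict[str, bool] = {}
    self_hits: dict[str, bool] = {}
    for row in hits.itertuples(index=False):
        good = row.evalue < e_cut
        if row.search in ("tblastn", "blastp") and good and row.outside_genus:
            out_hits[row.orf_id] = True
        if row.search == "self_blastp" and good and row.outside_genus:
            self_hits[row.orf_id] = True

    canon = ann[ann["orf_class"] == "canonical"]
    overlaps_canon: set = set()
    for oid, row in ann.iterrows():
        if row.orf_class == "canonical":
            continue
        same = canon[(canon["chrom"] == row.chrom)
                     & (canon["strand"] == row.strand)
                     & (canon["start"] < row.end)
                     & (canon["end"] > row.start)]
        if len(same):
            overlaps_canon.add(oid)

    labels = {}
    missing = []
    for oid, row in ann.iterrows():
        has_rfc = oid in rfc_t.index
        if not has_rfc:
            missing.append(oid)
            labels[oid] = "other"
            continue
        r = rfc_t.loc[oid]
        if r["mean_rfc"] > rfc_cons or out_hits.get(oid, False):
            labels[oid] = "conserved"
        elif (bool(row.get("translation_evidence", True))
              and not out_hits.get(oid, False)
              and not self_hits.get(oid, False)
              and oid not in overlaps_canon
              and r["rfc_distant1"] < rfc_denovo
              and r["rfc_distant2"] < rfc_denovo):
            labels[oid] = "de_novo"
        else:
            labels[oid] = "other"
    if missing:
        warnings.warn(f"{len(missing)} ORF(s) without RFC labeled other")
    return pd.Series(labels, name="conservation_label")


# ---------------------------------------------------------------------------
# orientation

@dataclass
class OrientationRecord:
    orf_id: str
    neighbor: str | None
    distance: int | None
    category: str

    @property
    def can_piggyback(self) -> bool:
        return self.category in CAN_PIGGYBACK


def _gap(s1, e1, s2, e2) -> int:
    """Gap between two half-open intervals; 0 when they overlap."""
    return max(0, max(s1, s2) - min(e1, e2))


def _pair_category(cons, dn) -> str | None:
    """Orientation of a de novo ORF relative to one conserved neighbor."""
    overlap = cons.start < dn.end and dn.start < cons.end
    same = cons.strand == dn.strand
    if overlap:
        return None if same else "antisense_overlap"
    # position in the conserved ORF's transcription direction
    if cons.strand == "+":
        downstream = dn.start >= cons.end
    else:
        downstream = dn.end <= cons.start
    if downstream:
        return "down_same" if same else "down_opposite"
    return "up_same" if same else "up_opposite"


def classify_orientation(orfs: pd.DataFrame, max_dist: int = 500
                         ) -> list[OrientationRecord]:
    """Orientation record per de novo ORF.

    Conserved ORFs on the same chromosome within ``max_dist`` bp (gap <=
    max_dist) vote on the category; a single category wins with the nearest
    neighbor attached, conflicting categories give ``ambiguous``, no
    in-range conserved ORF gives ``independent``.
    """
    cons = orfs[orfs["conservation_label"] == "conserved"]
    denovo = orfs[orfs["conservation_label"] == "de_novo"]
    records = []
    for dn in denovo.itertuples(index=False):
        near = []
        for c in cons.itertuples(index=False):
            if c.chrom != dn.chrom:
                continue
            gap = _gap(c.start, c.end, dn.start, dn.end)
            if gap > max_dist:
                continue
            cat = _pair_category(c, dn)
            if cat is None:
                continue
            near.append((gap, c.orf_id, cat))
        if not near:
            records.append(OrientationRecord(dn.orf_id, None, None,
                                             "independent"))
            continue
        cats = {cat for _, _, cat in near}
        if len(cats) > 1:
            records.append(OrientationRecord(dn.orf_id, None, None,
                                             "ambiguous"))
            continue
        gap, cid, cat = min(near)
        records.append(OrientationRecord(dn.orf_id, cid, gap, cat))
    return records


# ---------------------------------------------------------------------------
# TSS, binding, promoter sharing, terminators

def _tif_tss(t) -> int:
    return int(t.start) if t.strand == "+" else int(t.end) - 1


def _covering(orf, tifs: pd.DataFrame) -> pd.DataFrame:
    return tifs[(tifs["chrom"] == orf.chrom)
                & (tifs["strand"] == orf.strand)
                & (tifs["start"] <= orf.start)
                & (tifs["end"] >= orf.end)]


def tss_from_tifs(orf, tifs: pd.DataFrame) -> int | None:
    """Median TSS over covering isoforms (lower-middle for even counts)."""
    cov = _covering(orf, tifs)
    if cov.empty:
        return None
    tss = sorted(_tif_tss(t) for t in cov.itertuples(index=False))
    return tss[(len(tss) - 1) // 2]


def promoter_tf_binding(orf, tss: int | None, track: pd.DataFrame,
                        window: int = 200) -> set | None:
    """Factors with a binding site within ``window`` bp upstream of the TSS.

    The promoter window is [tss-window, tss) on '+' and (tss, tss+window]
    on '-'; a factor binds when any of its sites overlaps the window.
    Returns None when the TSS is unknown (ORF absent from the TIF data).
    """
    if tss is None:
        return None
    if orf.strand == "+":
        lo, hi = tss - window, tss
    else:
        lo, hi = tss + 1, tss + window + 1
    sel = track[(track["chrom"] == orf.chrom)
                & (track["start"] < hi) & (track["end"] > lo)]
    return set(sel["name"])


def shared_promoter(pair: OrientationRecord, orfs: pd.DataFrame,
                    tifs: pd.DataFrame) -> bool | None:
    """Do the two ORFs of a piggybacking-capable pair share a promoter?

    down_same / up_same: shared iff at least one isoform fully covers both
    ORFs. up_opposite: shared iff both ORFs are covered and no isoform
    covering one contains the TSS of any isoform covering the other
    (strictly divergent transcription). A conserved ORF absent from the
    isoform data makes the call missing (None); an absent de novo ORF
    means not shared.
    """
    if pair.category not in CAN_PIGGYBACK:
        raise ValueError(f"no promoter-sharing call for {pair.category}")
    ann = orfs.set_index("orf_id")
    dn, cons = ann.loc[pair.orf_id], ann.loc[pair.neighbor]
    cov_c = _covering(cons, tifs)
    if cov_c.empty:
        return None
    cov_d = _covering(dn, tifs)
    if cov_d.empty:
        return False
    if pair.category in ("down_same", "up_same"):
        both = cov_c[(cov_c["start"] <= min(cons.start, dn.start))
                     & (cov_c["end"] >= max(cons.end, dn.end))]
        return bool(len(both))
    # up_opposite: divergent isoforms with non-overlapping TSS regions
    for a, b in ((cov_c, cov_d), (cov_d, cov_c)):
        tss_b = [_tif_tss(t) for t in b.itertuples(index=False)]
        for t in a.itertuples(index=False):
            if any(t.start <= x < t.end for x in tss_b):
                return False
    return True


def shared_transcript_fraction(pair: OrientationRecord, orfs: pd.DataFrame,
                               tifs: pd.DataFrame) -> float:
    """Of the isoforms covering the de novo ORF, the fraction also covering
    the conserved neighbor (NaN when none cover the de novo ORF)."""
    ann = orfs.set_index("orf_id")
    dn, cons = ann.loc[pair.orf_id], ann.loc[pair.neighbor]
    cov_d = _covering(dn, tifs)
    if cov_d.empty:
        return float("nan")
    both = cov_d[(cov_d["start"] <= min(cons.start, dn.start))
                 & (cov_d["end"] >= max(cons.end, dn.end))]
    return len(both) / len(cov_d)


def terminator_between(pair: OrientationRecord, orfs: pd.DataFrame,
                       track: pd.DataFrame) -> bool:
    """Is a termination-factor site bound strictly inside the pair's gap?"""
    if pair.category != "down_same":
        raise ValueError("terminator calls apply to down_same pairs only")
    ann = orfs.set_index("orf_id")
    dn, cons = ann.loc[pair.orf_id], ann.loc[pair.neighbor]
    lo, hi = (cons.end, dn.start) if cons.end <= dn.start \
        else (dn.end, cons.start)
    if hi <= lo:
        warnings.warn("overlapping down_same pair has no gap")
        return False
    sel = track[(track["chrom"] == cons.chrom)
                & (track["start"] < hi) & (track["end"] > lo)]
    return bool(len(sel))


# ---------------------------------------------------------------------------
# piggybacking

def _contrast(x, y) -> dict:
    x = np.asarray([v for v in x if np.isfinite(v)], dtype=float)
    y = np.asarray([v for v in y if np.isfinite(v)], dtype=float)
    if x.size == 0 or y.size == 0:
        return {"cliffs_delta": float("nan"), "p": float("nan"),
                "n_x": int(x.size), "n_y": int(y.size)}
    return {"cliffs_delta": cliffs_delta(x, y), "p": mann_whitney(x, y).p,
            "n_x": int(x.size), "n_y": int(y.size)}


def piggyback_analysis(orientations: list, orfs: pd.DataFrame,
                       coex, median_tpm: pd.Series,
                       tifs: pd.DataFrame, terminator_track: pd.DataFrame,
                       enriched: dict | None = None,
                       anno=None) -> tuple[pd.DataFrame, dict]:
    """Per-pair piggybacking metrics plus the group contrasts.

    Metrics per single-orientation de novo ORF: its median TPM, its
    proportionality with the conserved neighbor, the Relevance similarity
    of the pair's enriched GO term sets (when GSEA results and an ontology
    are supplied), the promoter-sharing and terminator flags and the
    shared-transcript fraction. Contrasts (Cliff's delta + Mann-Whitney p):

    * expression / neighbor coexpression / similarity, can- vs
      cannot-piggyback orientations (expression background: independent de
      novo ORFs; coexpression background uses the convergent/antisense
      pairs);
    * neighbor coexpression, sharing vs non-sharing pairs within each
      piggybacking orientation;
    * shared-transcript fraction, terminator-present vs absent down-same
      pairs.
    """
    from .enrichment import go_relevance_similarity

    rows = []
    for rec in orientations:
        if rec.category in ("ambiguous",):
            continue
        row = {"orf_id": rec.orf_id, "neighbor": rec.neighbor,
               "category": rec.category,
               "can_piggyback": rec.can_piggyback,
               "median_tpm": float(median_tpm.get(rec.orf_id, np.nan)),
               "rho_neighbor": float("nan"), "go_similarity": float("nan"),
               "shares_promoter": None, "terminator_present": None,
               "shared_transcript_fraction": float("nan")}
        if rec.neighbor is not None:
            if rec.orf_id in coex.rho.index and rec.neighbor in coex.rho.index:
                row["rho_neighbor"] = float(
                    coex.rho.loc[rec.orf_id, rec.neighbor])
            if enriched is not None and anno is not None:
                row["go_similarity"] = go_relevance_similarity(
                    enriched.get(rec.orf_id, set()),
                    enriched.get(rec.neighbor, set()), anno)
            if rec.category in CAN_PIGGYBACK:
                row["shares_promoter"] = shared_promoter(rec, orfs, tifs)
                row["shared_transcript_fraction"] = \
                    shared_transcript_fraction(rec, orfs, tifs)
            if rec.category == "down_same":
                row["terminator_present"] = terminator_between(
                    rec, orfs, terminator_track)
        rows.append(row)
    table = pd.DataFrame(rows)
    contrasts: dict = {}
    if table.empty:
        return table, contrasts

    can = table[table["can_piggyback"]]
    cannot = table[table["category"].isin(
        ["down_opposite", "antisense_overlap"])]
    indep = table[table["category"] == "independent"]
    contrasts["expression_can_vs_independent"] = _contrast(
        can["median_tpm"], indep["median_tpm"])
    contrasts["rho_can_vs_cannot"] = _contrast(
        can["rho_neighbor"], cannot["rho_neighbor"])
    contrasts["similarity_can_vs_cannot"] = _contrast(
        can["go_similarity"], cannot["go_similarity"])
    for cat in sorted(CAN_PIGGYBACK):
        sub = table[table["category"] == cat]
        share = sub[sub["shares_promoter"] == True]   # noqa: E712
        noshare = sub[sub["shares_promoter"] == False]  # noqa: E712
        contrasts[f"rho_sharing_vs_not_{cat}"] = _contrast(
            share["rho_neighbor"], noshare["rho_neighbor"])
    ds = table[table["category"] == "down_same"]
    contrasts["shared_fraction_terminator_vs_not"] = _contrast(
        ds.loc[ds["terminator_present"] == True,      # noqa: E712
               "shared_transcript_fraction"],
        ds.loc[ds["terminator_present"] == False,     # noqa: E712
               "shared_transcript_fraction"])
    return table, contrasts
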