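"""Synthetic data with planted structure for the coexpression pipeline.

The generator emulates the statistical features of a yeast-like RNA-seq
compendium profiled over canonical and noncanonical ORFs:

* two expression strata — canonical ORFs are well expressed and detected in
  nearly every sample, noncanonical ORFs sit orders of magnitude lower and
  are conditionally expressed (an on/off indicator per ORF and sample);
* latent coexpression modules, including noncanonical-majority modules, via
  a per-module latent factor shared by its members;
* genomic neighbor pairs of a conserved ORF and a de novo ORF in the five
  orientations (down same, up same, up opposite, down opposite, antisense
  overlap) plus isolated "independent" de novo ORFs;
* transcriptional readthrough: down-same pairs that share a promoter leak a
  fraction lambda of the conserved neighbor's expected reads into the de
  novo ORF; pairs with a terminator bound in the intergenic gap do not;
* transcript isoforms (TIFs) consistent with the promoter-sharing flags,
  terminator and TF-binding tracks, a small GO DAG whose leaf terms mirror
  the planted modules, and a differential-expression table for the TF
  deletion analysis.

Every draw is routed through child generators spawned from one seed, so a
given :class:`SimConfig` reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio

ORIENTATIONS = [
    "down_same", "up_same", "up_opposite", "down_opposite",
    "antisense_overlap", "independent",
]

#: fraction of canonical members per planted module (cycled); gives both
#: canonical-majority and noncanonical-majority modules
MODULE_CANONICAL_FRACTIONS = [0.9, 0.1, 0.9, 0.1, 0.5]


class ConfigurationError(ValueError):
    """Requested synthetic layout cannot be satisfied."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Expression baselines are on the natural-log relative-abundance scale;
    the two class means are separated by ~2.5 log units so canonical ORFs
    occupy a much higher TPM stratum, mirroring the detection-sparsity
    contrast between the classes.
    """

    seed: int = 0
    n_canonical: int = 150
    n_noncanonical: int = 150
    n_samples: int = 500
    n_modules: int = 5
    module_size_range: tuple = (20, 30)
    canonical_log_tpm_mean: float = 3.0
    canonical_log_tpm_sd: float = 0.7
    noncanonical_log_tpm_mean: float = 0.5
    noncanonical_log_tpm_sd: float = 0.7
    detection_fraction_noncanonical: float = 0.45
    depth_range: tuple = (100_000, 300_000)
    readthrough_fraction: float = 0.5
    orientation_counts: dict = field(default_factory=lambda: {
        "down_same": 20, "up_same": 8, "up_opposite": 8,
        "down_opposite": 6, "antisense_overlap": 6, "independent": 10,
    })
    terminator_fraction: float = 0.5
    noise_sd: float = 0.3
    module_loading: float = 1.5
    dispersion: float = 0.0
    n_tf_targets: int = 25
    tif_absent_fraction: float = 0.02
    off_rate: float = 0.1

    def __post_init__(self):
        counts = [self.n_canonical, self.n_noncanonical, self.n_samples,
                  self.n_modules]
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all counts must be positive")
        lo, hi = self.module_size_range
        if lo < 3 or hi < lo:
            raise ConfigurationError("module sizes must be >= 3")
        for f in (self.detection_fraction_noncanonical,
                  self.readthrough_fraction, self.terminator_fraction,
                  self.tif_absent_fraction):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        if self.detection_fraction_noncanonical == 0:
            raise ConfigurationError("detection fraction must be > 0")
        unknown = set(self.orientation_counts) - set(ORIENTATIONS)
        if unknown:
            raise ConfigurationError(f"unknown orientations: {unknown}")
        n_pairs = sum(self.orientation_counts.get(o, 0)
                      for o in ORIENTATIONS if o != "independent")
        n_indep = self.orientation_counts.get("independent", 0)
        if n_pairs > self.n_canonical:
            raise ConfigurationError("not enough canonical ORFs for pairs")
        if n_pairs + n_indep > self.n_noncanonical:
            raise ConfigurationError("not enough noncanonical ORFs for pairs")


@dataclass
class GroundTruth:
    """Planted structure, recorded exactly as emitted in the files."""

    module_assignment: dict          # orf_id -> module index (0 = none)
    orientation: dict                # de novo orf_id -> orientation category
    partner: dict                    # de novo orf_id -> conserved orf_id|None
    shares_promoter: dict            # de novo orf_id -> bool
    terminator_present: dict         # de novo orf_id -> bool
    tf_targets: dict                 # factor -> sorted list of orf_ids
    tif_absent: list                 # orf_ids with no covering TIF

    def to_json(self, path) -> None:
        nio.write_json(asdict(self), path)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**nio.read_json(path))

    def module_sets(self) -> dict:
        """Gene sets of the planted modules, keyed ``module_<k>``."""
        out: dict[str, set] = {}
        for orf, m in self.module_assignment.items():
            if m > 0:
                out.setdefault(f"module_{m}", set()).add(orf)
        return out


def _rngs(config: SimConfig, n: int):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(n)]


# ---------------------------------------------------------------------------
# genome layout

_CONS_LEN = 900
_DENOVO_LEN = 300
_BLOCK_SPACING = 4000


def _place_pair(orientation: str, cursor: int, c_strand: str, gap: int):
    """Coordinates (conserved, de novo, de novo strand) for one pair block.

    Positions are laid out relative to the conserved ORF's transcription
    direction: "down" is past its stop codon, "up" is before its start.
    """
    flip = {"+": "-", "-": "+"}
    cs = cursor + _DENOVO_LEN + 600          # room for an upstream de novo
    ce = cs + _CONS_LEN
    if c_strand == "+":
        down = (ce + gap, ce + gap + _DENOVO_LEN)
        up = (cs - gap - _DENOVO_LEN, cs - gap)
    else:
        down = (cs - gap - _DENOVO_LEN, cs - gap)
        up = (ce + gap, ce + gap + _DENOVO_LEN)
    if orientation == "down_same":
        d, ds = down, c_strand
    elif orientation == "up_same":
        d, ds = up, c_strand
    elif orientation == "up_opposite":
        d, ds = up, flip[c_strand]
    elif orientation == "down_opposite":
        d, ds = down, flip[c_strand]
    elif orientation == "antisense_overlap":
        d, ds = (cs + 200, cs + 200 + _DENOVO_LEN), flip[c_strand]
    else:  # pragma: no cover - guarded by caller
        raise ConfigurationError(orientation)
    return (cs, ce), d, ds


def generate_annotation(config: SimConfig):
    """Lay out the synthetic genome and return (annotation, ground truth).

    Chromosome ``chrM`` carries the module/background ORFs, ``chrP`` the
    conserved/de novo neighbor pairs (intergenic gap < 500 bp), ``chrI``
    the independent de novo ORFs (no conserved ORF within 500 bp of any of
    them, by construction on a conserved-free chromosome).
    """
    rng_layout, rng_mod = _rngs(config, 8)[:2]
    oc = {o: int(config.orientation_counts.get(o, 0)) for o in ORIENTATIONS}
    n_pair_cons = sum(v for o, v in oc.items() if o != "independent")
    n_pair_dn = n_pair_cons
    n_indep = oc["independent"]

    rows = []
    truth_orient: dict[str, str] = {}
    truth_partner: dict[str, str | None] = {}

    # --- paired conserved / de novo ORFs on chrP
    cursor, k = 1000, 0
    for orientation in ORIENTATIONS:
        if orientation == "independent":
            continue
        for _ in range(oc[orientation]):
            c_strand = "+" if k % 2 == 0 else "-"
            gap = int(rng_layout.integers(50, 451))
            (cs, ce), (ds, de), d_strand = _place_pair(
                orientation, cursor, c_strand, gap)
            cid, did = f"cons_{k:03d}", f"denovo_{k:03d}"
            rows.append((cid, "chrP", cs, ce, c_strand, "canonical",
                         "conserved", True))
            rows.append((did, "chrP", ds, de, d_strand, "noncanonical",
                         "de_novo", True))
            truth_orient[did] = orientation
            truth_partner[did] = cid
            cursor += _BLOCK_SPACING
            k += 1

    # --- independent de novo ORFs on a conserved-free chromosome
    cursor = 1000
    for j in range(n_indep):
        did = f"denovo_i{j:03d}"
        rows.append((did, "chrI", cursor, cursor + _DENOVO_LEN, "+",
                     "noncanonical", "de_novo", True))
        truth_orient[did] = "independent"
        truth_partner[did] = None
        cursor += 2000 + _DENOVO_LEN

    # --- module / background ORFs on chrM
    n_bg_c = config.n_canonical - n_pair_cons
    n_bg_n = config.n_noncanonical - n_pair_dn - n_indep
    cursor = 1000
    bg_canon, bg_noncanon = [], []
    for j in range(n_bg_c + n_bg_n):
        canonical = j < n_bg_c
        length = int(rng_layout.integers(600, 1501) if canonical
                     else rng_layout.integers(150, 601))
        oid = f"c_{j:03d}" if canonical else f"n_{j - n_bg_c:03d}"
        rows.append((oid, "chrM", cursor, cursor + length,
                     "+" if j % 2 == 0 else "-",
                     "canonical" if canonical else "noncanonical",
                     "conserved" if canonical else "other", True))
        (bg_canon if canonical else bg_noncanon).append(oid)
        cursor += length + 2000

    annotation = pd.DataFrame(rows, columns=nio.ANNOTATION_COLUMNS)

    # --- planted modules over the background pool
    module_assignment = {oid: 0 for oid in annotation["orf_id"]}
    canon_pool, noncanon_pool = list(bg_canon), list(bg_noncanon)
    lo, hi = config.module_size_range
    for m in range(1, config.n_modules + 1):
        size = int(rng_mod.integers(lo, hi + 1))
        frac_c = MODULE_CANONICAL_FRACTIONS[(m - 1) % len(MODULE_CANONICAL_FRACTIONS)]
        n_c = int(round(size * frac_c))
        n_n = size - n_c
        if n_c > len(canon_pool) or n_n > len(noncanon_pool):
            raise ConfigurationError(
                "module sizes exceed available background ORFs")
        take_c = [canon_pool.pop(int(i)) for i in
                  sorted(rng_mod.choice(len(canon_pool), n_c, replace=False),
                         reverse=True)]
        take_n = [noncanon_pool.pop(int(i)) for i in
                  sorted(rng_mod.choice(len(noncanon_pool), n_n, replace=False),
                         reverse=True)]
        for oid in take_c + take_n:
            module_assignment[oid] = m

    truth = GroundTruth(
        module_assignment=module_assignment,
        orientation=truth_orient,
        partner=truth_partner,
        shares_promoter={},
        terminator_present={},
        tf_targets={},
        tif_absent=[],
    )
    _assign_pair_flags(truth, config)
    return annotation, truth


def _assign_pair_flags(truth: GroundTruth, config: SimConfig) -> None:
    """Promoter-sharing and terminator flags per de novo ORF.

    Down-same pairs either read through (share a promoter/transcript) or
    are interrupted by a bound terminator; up-same and up-opposite pairs
    share a promoter with probability 1/2; convergent and antisense
    orientations cannot piggyback and never share.
    """
    rng = _rngs(config, 8)[2]
    for did, orientation in truth.orientation.items():
        if orientation == "down_same":
            term = bool(rng.random() < config.terminator_fraction)
            truth.terminator_present[did] = term
            truth.shares_promoter[did] = not term
        elif orientation in ("up_same", "up_opposite"):
            truth.terminator_present[did] = False
            truth.shares_promoter[did] = bool(rng.random() < 0.5)
        else:
            truth.terminator_present[did] = False
            truth.shares_promoter[did] = False


# ---------------------------------------------------------------------------
# counts

def generate_counts(config: SimConfig, annotation: pd.DataFrame,
                    truth: GroundTruth):
    """Draw the ORF x sample count matrix.

    Log relative expression is class baseline + module loading x latent
    factor + Gaussian noise; noncanonical ORFs are "on" only in a
    ``detection_fraction_noncanonical`` subset of samples and draw from a
    near-zero Poisson rate when off. Expected counts are the per-sample
    depth times the relative abundance; sharing down-same pairs receive an
    additive ``readthrough_fraction`` of the conserved neighbor's expected
    count.
    """
    rng = _rngs(config, 8)[3]
    orfs = annotation["orf_id"].to_numpy()
    classes = annotation["orf_class"].to_numpy()
    n_orf, n_smp = len(orfs), config.n_samples
    idx = {o: i for i, o in enumerate(orfs)}

    is_canon = classes == "canonical"
    baseline = np.where(
        is_canon,
        rng.normal(config.canonical_log_tpm_mean,
                   config.canonical_log_tpm_sd, n_orf),
        rng.normal(config.noncanonical_log_tpm_mean,
                   config.noncanonical_log_tpm_sd, n_orf),
    )
    factors = rng.normal(size=(config.n_modules, n_smp))
    module = np.array([truth.module_assignment[o] for o in orfs])
    log_expr = baseline[:, None] + rng.normal(0.0, config.noise_sd,
                                              (n_orf, n_smp))
    in_mod = module > 0
    log_expr[in_mod] += config.module_loading * factors[module[in_mod] - 1]

    on = np.ones((n_orf, n_smp), dtype=bool)
    noncanon = ~is_canon
    on[noncanon] = rng.random((noncanon.sum(), n_smp)) \
        < config.detection_fraction_noncanonical

    rel = np.where(on, np.exp(log_expr), 0.0)
    depth = rng.uniform(*config.depth_range, n_smp)
    mu = depth[None, :] * rel / rel.sum(axis=0, keepdims=True)
    mu[~on] = config.off_rate

    # readthrough from the conserved partner onto sharing down-same de novo
    lam = config.readthrough_fraction
    if lam > 0:
        for did, orientation in truth.orientation.items():
            if (orientation == "down_same" and truth.shares_promoter[did]
                    and not truth.terminator_present[did]):
                mu[idx[did]] += lam * mu[idx[truth.partner[did]]]

    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        mu = rng.gamma(shape, mu / shape)
    counts = rng.poisson(mu)
    return pd.DataFrame(counts, index=pd.Index(orfs, name="orf_id"),
                        columns=[f"S{j:04d}" for j in range(n_smp)])


# ---------------------------------------------------------------------------
# transcript isoforms

def generate_isoforms(annotation: pd.DataFrame, truth: GroundTruth,
                      config: SimConfig) -> pd.DataFrame:
    """Emit TIF intervals (BED-like) consistent with the sharing flags.

    Every ORF not flagged TIF-absent gets two covering isoforms with small
    jittered flanks; sharing down-same/up-same pairs additionally get two
    isoforms spanning both ORFs; sharing up-opposite pairs get divergent
    isoforms whose TSSs stay outside the partner's isoforms, while
    non-sharing up-opposite pairs get a conserved isoform that reaches past
    the de novo TSS.
    """
    rng = _rngs(config, 8)[4]
    ann = annotation.set_index("orf_id")

    # flag some background noncanonical ORFs as missing from the TIF data
    bg_non = [o for o in annotation["orf_id"]
              if o.startswith("n_")]
    n_absent = int(round(config.tif_absent_fraction * len(bg_non)))
    absent = set(rng.choice(bg_non, n_absent, replace=False)) if n_absent else set()
    truth.tif_absent = sorted(absent)

    records = []

    def flank():
        return int(rng.integers(20, 121))

    def add(chrom, start, end, name, strand):
        records.append((chrom, int(start), int(end), name, 0, strand))

    paired = set(truth.partner.values()) - {None}
    for oid, row in ann.iterrows():
        if oid in absent:
            continue
        special_up_opposite = (
            oid in truth.orientation
            and truth.orientation[oid] == "up_opposite"
        ) or oid in paired
        # plain covering isoforms; pair members get tight flanks so that
        # up-opposite TSS geometry is controlled below
        f1, f2 = (10, 10) if special_up_opposite else (flank(), flank())
        for t in range(2):
            add(row.chrom, row.start - f1 - t * 5, row.end + f2 + t * 5,
                f"tif_{oid}_{t}", row.strand)

    for did, orientation in truth.orientation.items():
        if did in absent or orientation == "independent":
            continue
        cid = truth.partner[did]
        c, d = ann.loc[cid], ann.loc[did]
        lo = min(c.start, d.start)
        hi = max(c.end, d.end)
        if orientation in ("down_same", "up_same") and truth.shares_promoter[did]:
            for t in range(2):
                add(c.chrom, lo - flank(), hi + flank(),
                    f"tif_joint_{did}_{t}", c.strand)
        if orientation == "up_opposite" and not truth.shares_promoter[did]:
            # conserved isoform runs past the de novo ORF's TSS region
            add(c.chrom, lo - 40, hi + 40, f"tif_over_{did}", c.strand)
    return pd.DataFrame(records, columns=nio.BED_COLUMNS)


# ---------------------------------------------------------------------------
# binding tracks

def generate_tracks(annotation: pd.DataFrame, truth: GroundTruth,
                    config: SimConfig, tifs: pd.DataFrame):
    """Terminator and TF binding-site tracks (BED).

    Terminator sites (Pcf11/Nrd1-like) land strictly inside the intergenic
    gap of terminator-flagged down-same pairs and nowhere else. TF sites
    land within 200 bp upstream of the TSS of each designated target ORF,
    plus decoy sites far from every ORF.
    """
    from .context import tss_from_tifs  # local import; no cycle at module load

    rng = _rngs(config, 8)[5]
    ann = annotation.set_index("orf_id")

    term_rows = []
    for did, orientation in truth.orientation.items():
        if orientation != "down_same" or not truth.terminator_present[did]:
            continue
        c, d = ann.loc[truth.partner[did]], ann.loc[did]
        gap_lo, gap_hi = (c.end, d.start) if c.end <= d.start else (d.end, c.start)
        pos = int((gap_lo + gap_hi) // 2)
        term_rows.append((c.chrom, pos, pos + 1, "Pcf11", 0, "."))
    terminators = pd.DataFrame(term_rows, columns=nio.BED_COLUMNS)

    # targets drawn from the background chromosome only: promoter windows of
    # divergent pair members can overlap, which would blur the target labels
    covered = [o for o, c in zip(annotation["orf_id"], annotation["chrom"])
               if c == "chrM" and o not in set(truth.tif_absent)]
    n_targets = min(config.n_tf_targets, len(covered))
    targets = sorted(rng.choice(covered, n_targets, replace=False))
    tf_rows = []
    for oid in targets:
        row = ann.loc[oid]
        tss = tss_from_tifs(row, tifs)
        if tss is None:
            continue
        offset = int(rng.integers(20, 180))
        if row.strand == "+":
            start = tss - offset          # inside [tss-200, tss)
        else:
            start = tss + offset - 4      # inside (tss, tss+200]
        tf_rows.append((row.chrom, start, start + 5, "TF1", 0, "."))
    # decoys on an empty stretch of chrM
    far = int(ann.loc[ann.chrom == "chrM", "end"].max() + 50_000)
    for j in range(5):
        tf_rows.append(("chrM", far + j * 1000, far + j * 1000 + 5, "TF1", 0, "."))
    truth.tf_targets = {"TF1": [t for t in targets
                                if tss_from_tifs(ann.loc[t], tifs) is not None]}
    tf_sites = pd.DataFrame(tf_rows, columns=nio.BED_COLUMNS)
    return tf_sites, terminators


# ---------------------------------------------------------------------------
# ontology and DE table

def generate_ontology(truth: GroundTruth, config: SimConfig,
                      annotation: pd.DataFrame, min_term_size: int = 20):
    """Small GO-like DAG aligned to the planted modules.

    Root -> two mid-level terms -> one leaf per module. Each leaf is
    annotated to its module's canonical members, padded with random
    canonical non-members up to ``min_term_size`` genes.
    """
    rng = _rngs(config, 8)[6]
    classes = annotation.set_index("orf_id")["orf_class"]
    canonical = [o for o in classes.index if classes[o] == "canonical"]

    terms = {
        "GO:0000001": {"name": "biological_process", "is_a": []},
        "GO:0000002": {"name": "module process", "is_a": ["GO:0000001"]},
        "GO:0000003": {"name": "housekeeping process", "is_a": ["GO:0000001"]},
    }
    direct: dict[str, set] = {}
    module_terms: dict[str, int] = {}
    mod_sets = truth.module_sets()
    for m in range(1, config.n_modules + 1):
        tid = f"GO:{100 + m:07d}"
        terms[tid] = {"name": f"module {m} process", "is_a": ["GO:0000002"]}
        module_terms[tid] = m
        members = mod_sets.get(f"module_{m}", set())
        genes = {g for g in members if classes[g] == "canonical"}
        pool = [g for g in canonical if g not in genes]
        # pad toward min_term_size; tiny studies may not have enough genes
        need = min(max(0, min_term_size - len(genes)), len(pool))
        if need:
            genes |= set(rng.choice(pool, need, replace=False))
        direct[tid] = genes
    other = [g for g in canonical
             if all(g not in direct[t] for t in direct)]
    n_other = min(max(min_term_size, 25), len(other))
    if n_other:
        direct["GO:0000003"] = set(rng.choice(other, n_other, replace=False))
    return terms, direct, module_terms


def generate_de_table(truth: GroundTruth, config: SimConfig,
                      annotation: pd.DataFrame, factor: str = "TF1"
                      ) -> pd.DataFrame:
    """Differential-expression table for a TF deletion experiment.

    Targets of ``factor`` get log fold changes below -0.5 with small
    adjusted p-values; everything else is centered at zero and
    nonsignificant.
    """
    rng = _rngs(config, 8)[7]
    targets = set(truth.tf_targets.get(factor, []))
    rows = []
    for oid in annotation["orf_id"]:
        if oid in targets:
            lfc = -float(rng.uniform(0.8, 2.0))
            padj = float(10 ** -rng.uniform(2.5, 6.0))
        else:
            lfc = float(np.clip(rng.normal(0.0, 0.1), -0.45, 0.45))
            padj = float(rng.uniform(0.2, 1.0))
        rows.append((oid, lfc, padj))
    return pd.DataFrame(rows, columns=["orf_id", "lfc", "padj"])


# ---------------------------------------------------------------------------
# bundle

@dataclass
class SimResult:
    config: SimConfig
    annotation: pd.DataFrame
    truth: GroundTruth
    counts: pd.DataFrame
    tifs: pd.DataFrame
    tf_sites: pd.DataFrame
    terminators: pd.DataFrame
    ontology_terms: dict
    term_annotations: dict
    module_terms: dict
    de_table: pd.DataFrame

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        nio.write_counts_tsv(self.counts, out / "counts.tsv")
        nio.write_gff3(self.annotation, out / "orfs.gff3")
        nio.write_bed(self.tifs, out / "tifs.bed")
        nio.write_bed(self.tf_sites, out / "tf_sites.bed")
        nio.write_bed(self.terminators, out / "terminators.bed")
        nio.write_obo(self.ontology_terms, out / "go.obo")
        nio.write_gaf({t: g for t, g in self.term_annotations.items()},
                      out / "annotations.gaf")
        self.de_table.to_csv(out / "de_table.tsv", sep="\t", index=False)
        self.truth.to_json(out / "truth.json")


def simulate(config: SimConfig) -> SimResult:
    """Run every generator stage and return the bundled synthetic study."""
    annotation, truth = generate_annotation(config)
    counts = generate_counts(config, annotation, truth)
    tifs = generate_isoforms(annotation, truth, config)
    tf_sites, terminators = generate_tracks(annotation, truth, config, tifs)
    terms, direct, module_terms = generate_ontology(truth, config, annotation)
    de_table = generate_de_table(truth, config, annotation)
    return SimResult(config, annotation, truth, counts, tifs, tf_sites,
                     terminators, terms, direct, module_terms, de_table)
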