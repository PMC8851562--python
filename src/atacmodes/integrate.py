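"""Cross-dataset integration of expression, TF binding and accessibility.

The end point is a per-gene regulatory-mode call for a nuclear receptor
studied by knockout and by pharmacological agonist: each gene's joint
response across the two contrasts, gated on direct ChIP binding evidence,
places it in one of the discordant/nonresponsive segments

    ligand-activated            down in KO, up with agonist, bound
    ligand-repressed            up in KO, down with agonist, bound
    basal-required-nonresponsive   down in KO, agonist-unchanged, bound
    basal-repressed-nonresponsive  up in KO, agonist-unchanged, bound
    agonist-only                KO-unchanged, agonist-responsive, bound
    indirect                    differentially expressed without binding

Supporting views: binding-overlap proportions by DE class (Fisher exact),
accessibility change at binding-site peaks by DE class (Mann-Whitney U),
per-gene binding-site counts, and flagging of large accessibility losses
at binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact, mannwhitneyu

from .annotate import GeneIndex
from .io_core import (BindingSiteSet, DataError, DETable, GeneModel, PeakSet,
                      logger)
from .motifs import OccurrenceMatrix, subset_enrichment
from .peak_stats import RankedPeaks, rpkm, top_n

DIRECT_MODES = ("ligand-activated", "ligand-repressed",
                "basal-required-nonresponsive", "basal-repressed-nonresponsive")
ALL_MODES = DIRECT_MODES + ("agonist-only", "indirect", "none")


def classify_de(de: DETable, alpha: float = 0.05,
                lfc_threshold: float = 0.0) -> pd.Series:
    """Per-gene class in {down, up, unchanged}: significant (adjusted p <
    alpha) with log2FC beyond +/- lfc_threshold; everything else unchanged.
    Genes absent from the table are simply absent (untested)."""
    t = de.table
    cls = pd.Series("unchanged", index=t.index, name=f"class_{de.contrast_name}")
    sig = t["adjusted_p"] < alpha
    cls[sig & (t["log2_fold_change"] < -lfc_threshold)] = "down"
    cls[sig & (t["log2_fold_change"] > lfc_threshold)] = "up"
    return cls


@dataclass
class BindingAssignment:
    """Per-gene binding-site counts for the basal and agonist site sets."""

    counts: pd.DataFrame      # index gene_id; columns basal, agonist
    site_genes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # condition -> [(site_key, gene_id)] assignment trace

    def bound_genes(self, condition: str) -> set[str]:
        return set(self.counts.index[self.counts[condition] > 0])

    def evidence(self, gene: str) -> str:
        if gene in self.counts.index:
            row = self.counts.loc[gene]
            if row.get("basal", 0) > 0:
                return "basal"
            if row.get("agonist", 0) > 0:
                return "agonist-only"
        return "none"


def assign_binding(genes: list[GeneModel], site_sets: list[BindingSiteSet],
                   rule: str = "nearest", promoter_upstream: int = 1000,
                   index: GeneIndex | None = None) -> BindingAssignment:
    """Assign each binding site to a target gene.

    rule="nearest": the site midpoint's nearest-TSS gene (ties to the
    lexicographically smaller id). rule="span": any gene whose span extended
    by the promoter window contains the midpoint; falls back to nearest when
    none does.
    """
    if rule not in {"nearest", "span"}:
        raise DataError(f"unknown binding assignment rule {rule!r}")
    index = index or GeneIndex(genes, promoter_upstream=promoter_upstream)
    span_trees: dict[str, IntervalTree] = {}
    if rule == "span":
        for g in genes:
            span = g.span
            lo = span.start - (promoter_upstream if g.strand == "+" else 0)
            hi = span.end + (promoter_upstream if g.strand == "-" else 0)
            span_trees.setdefault(g.chrom, IntervalTree())[max(lo, 0):hi] = g.gene_id
    counts = pd.DataFrame(0, index=pd.Index([g.gene_id for g in genes],
                                            name="gene_id"),
                          columns=[s.condition_label for s in site_sets])
    trace: dict[str, list[tuple[str, str]]] = {}
    for site_set in site_sets:
        pairs = []
        for site in site_set.sites:
            mid = site.midpoint
            assigned: list[str] = []
            if rule == "span":
                tree = span_trees.get(site.chrom)
                assigned = sorted(iv.data for iv in tree[mid]) if tree else []
            if not assigned:
                gid, _ = index.nearest_gene(site.chrom, mid)
                assigned = [gid] if gid else []
            for gid in assigned:
                counts.loc[gid, site_set.condition_label] += 1
                pairs.append((f"{site.chrom}:{site.start}-{site.end}", gid))
        trace[site_set.condition_label] = pairs
    return BindingAssignment(counts=counts, site_genes=trace)


def binding_by_class(classes: pd.Series, binding: BindingAssignment
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportion of genes in each DE class with >= 1 binding site, for each
    site set, plus pairwise Fisher exact tests between classes."""
    universe = classes.index
    rows, tests = [], []
    for cond in binding.counts.columns:
        bound = binding.bound_genes(cond)
        by_class = {}
        for cls in ("down", "up", "unchanged"):
            members = universe[classes == cls]
            n_bound = sum(g in bound for g in members)
            prop = n_bound / len(members) if len(members) else np.nan
            if len(members) == 0:
                logger.warning("binding_by_class: empty class %r", cls)
            by_class[cls] = (n_bound, len(members))
            rows.append({"site_set": cond, "de_class": cls, "n_genes": len(members),
                         "n_bound": n_bound, "proportion": prop})
        pairs = [("down", "up"), ("down", "unchanged"), ("up", "unchanged")]
        for a, b in pairs:
            (ka, na), (kb, nb) = by_class[a], by_class[b]
            if na == 0 or nb == 0:
                p = np.nan
            else:
                _, p = fisher_exact([[ka, na - ka], [kb, nb - kb]])
            tests.append({"site_set": cond, "class_a": a, "class_b": b,
                          "fisher_p": p})
    return pd.DataFrame(rows), pd.DataFrame(tests)


def binding_site_peaks(peakset: PeakSet, sites: BindingSiteSet,
                       annotations: pd.DataFrame, condition_a: str,
                       condition_b: str) -> pd.DataFrame:
    """ATAC peaks overlapping any binding site (any-overlap), with their
    RPKM change (condition_b - condition_a), nearest gene and feature
    class."""
    mat = rpkm(peakset)
    idx_a = peakset.sample_indices(condition_a)
    idx_b = peakset.sample_indices(condition_b)
    vals = mat.to_numpy()
    diff = vals[:, idx_b].mean(axis=1) - vals[:, idx_a].mean(axis=1)
    trees: dict[str, IntervalTree] = {}
    for site in sites.sites:
        trees.setdefault(site.chrom, IntervalTree())[site.start:site.end] = True
    keep = []
    for i, p in enumerate(peakset.peaks):
        tree = trees.get(p.chrom)
        if tree is not None and tree[p.start:p.end]:
            keep.append(i)
    if not keep:
        raise DataError("no ATAC peaks overlap the binding-site set")
    ids = [peakset.peak_ids[i] for i in keep]
    out = pd.DataFrame({"diff": diff[keep]}, index=pd.Index(ids, name="peak_id"))
    out["nearest_gene"] = annotations.loc[ids, "nearest_gene"]
    out["feature_class"] = annotations.loc[ids, "feature_class"]
    return out


def accessibility_at_binding(peakset: PeakSet, sites: BindingSiteSet,
                             classes: pd.Series, annotations: pd.DataFrame,
                             condition_a: str, condition_b: str
                             ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Distribution of accessibility change at binding-site peaks, grouped
    by the DE class of the peak's nearest gene; Mann-Whitney U against the
    unchanged class and down-vs-up; plus the global fraction of binding-site
    peaks losing accessibility."""
    bp = binding_site_peaks(peakset, sites, annotations, condition_a, condition_b)
    bp = bp.assign(de_class=bp["nearest_gene"].map(classes).fillna("unchanged"))
    frac_losing = float((bp["diff"] < 0).mean())
    rows = []
    groups = {cls: bp.loc[bp["de_class"] == cls, "diff"].to_numpy()
              for cls in ("down", "up", "unchanged")}
    for cls, vals in groups.items():
        rows.append({"de_class": cls, "n_peaks": vals.size,
                     "mean": float(vals.mean()) if vals.size else np.nan,
                     "median": float(np.median(vals)) if vals.size else np.nan})
    tests = []
    for a, b in (("down", "unchanged"), ("up", "unchanged"), ("down", "up")):
        va, vb = groups[a], groups[b]
        if va.size and vb.size:
            _, p = mannwhitneyu(va, vb, alternative="two-sided")
        else:
            p = np.nan
        tests.append({"class_a": a, "class_b": b, "mannwhitney_p": p})
    return pd.DataFrame(rows).set_index("de_class"), pd.DataFrame(tests), frac_losing


def flag_large_loss(peakset: PeakSet, sites: BindingSiteSet,
                    condition_a: str, condition_b: str,
                    threshold_rpkm: float = 10.0) -> list[str]:
    """Binding-site-overlapping peaks whose mean RPKM dropped by at least
    ``threshold_rpkm`` from condition_a to condition_b."""
    mat = rpkm(peakset)
    idx_a = peakset.sample_indices(condition_a)
    idx_b = peakset.sample_indices(condition_b)
    vals = mat.to_numpy()
    loss = vals[:, idx_a].mean(axis=1) - vals[:, idx_b].mean(axis=1)
    trees: dict[str, IntervalTree] = {}
    for site in sites.sites:
        trees.setdefault(site.chrom, IntervalTree())[site.start:site.end] = True
    flagged = []
    for i, p in enumerate(peakset.peaks):
        tree = trees.get(p.chrom)
        if tree is not None and tree[p.start:p.end] and loss[i] >= threshold_rpkm:
            flagged.append(peakset.peak_ids[i])
    return flagged


@dataclass
class ModeAssignment:
    table: pd.DataFrame  # index gene_id; columns mode, binding_evidence

    def genes_in_mode(self, mode: str) -> list[str]:
        return list(self.table.index[self.table["mode"] == mode])

    def segment_counts(self) -> pd.Series:
        return self.table["mode"].value_counts().reindex(ALL_MODES, fill_value=0)


def classify_modes(ko_classes: pd.Series, agonist_classes: pd.Series,
                   binding: BindingAssignment) -> ModeAssignment:
    """Joint (knockout class x agonist class) segmentation gated on binding.

    Direct modes require binding evidence (basal or agonist-only site);
    DE genes without any binding are "indirect". Genes unchanged in both
    contrasts, or with a concordant KO/agonist response (outside the four
    segments), are "none". Genes untested in the agonist contrast are
    treated as agonist-unchanged.
    """
    universe = ko_classes.index
    agonist = agonist_classes.reindex(universe).fillna("unchanged")
    rows = []
    for gene in universe:
        ko, ag = ko_classes[gene], agonist[gene]
        evidence = binding.evidence(gene)
        bound = evidence != "none"
        if ko == "down" and ag == "up" and bound:
            mode = "ligand-activated"
        elif ko == "up" and ag == "down" and bound:
            mode = "ligand-repressed"
        elif ko == "down" and ag == "unchanged" and bound:
            mode = "basal-required-nonresponsive"
        elif ko == "up" and ag == "unchanged" and bound:
            mode = "basal-repressed-nonresponsive"
        elif ko == "unchanged" and ag in {"up", "down"} and bound:
            mode = "agonist-only"
        elif (ko in {"up", "down"} or ag in {"up", "down"}) and not bound:
            mode = "indirect"
        else:
            mode = "none"
        rows.append({"gene_id": gene, "mode": mode, "binding_evidence": evidence,
                     "ko_class": ko, "agonist_class": ag})
    return ModeAssignment(pd.DataFrame(rows).set_index("gene_id"))


def unit_variance_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise (x - mean) / sd, the scaling used for mode heatmaps."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((values - mean) / sd, index=matrix.index,
                        columns=matrix.columns)


def segment_summary(modes: ModeAssignment, occ: OccurrenceMatrix,
                    site_peaks: pd.DataFrame, top_k: int = 3) -> dict[str, dict]:
    """Per-segment report: gene list, top-k motif enrichments of the
    segment's binding-site peaks against all binding-site peaks, promoter
    fraction of those peaks with a Fisher test against the complementary
    segments, and their mean accessibility change."""
    background = [p for p in site_peaks.index if p in occ.presence.index]
    reports: dict[str, dict] = {}
    for mode in DIRECT_MODES:
        genes = modes.genes_in_mode(mode)
        seg_peaks = [p for p in background
                     if site_peaks.loc[p, "nearest_gene"] in set(genes)]
        report: dict = {"mode": mode, "n_genes": len(genes), "genes": genes,
                        "n_binding_peaks": len(seg_peaks)}
        if len(genes) < 2 or not seg_peaks:
            report["note"] = "too few genes/peaks; tests suppressed"
            reports[mode] = report
            continue
        enr = subset_enrichment(occ, seg_peaks, background)
        report["top_motifs"] = [
            {"motif": m, "p": float(r["p"]), "fold": float(r["fold"])}
            for m, r in enr.head(top_k).iterrows()]
        in_prom = int((site_peaks.loc[seg_peaks, "feature_class"] == "promoter").sum())
        rest = [p for p in background if p not in set(seg_peaks)]
        rest_prom = int((site_peaks.loc[rest, "feature_class"] == "promoter").sum())
        if rest:
            _, fisher_p = fisher_exact(
                [[in_prom, len(seg_peaks) - in_prom],
                 [rest_prom, len(rest) - rest_prom]])
        else:
            fisher_p = np.nan
        report["promoter_fraction"] = in_prom / len(seg_peaks)
        report["promoter_fisher_p"] = float(fisher_p)
        report["mean_accessibility_change"] = float(
            site_peaks.loc[seg_peaks, "diff"].mean())
        reports[mode] = report
    return reports


def promoter_gain_analysis(ranked: RankedPeaks, annotations: pd.DataFrame,
                           occ: OccurrenceMatrix, binding: BindingAssignment,
                           motif_id: str, n_top: int = 1000,
                           ko_classes: pd.Series | None = None) -> dict:
    """Among the top-N gain peaks carrying a given motif: the associated
    (nearest) genes and what fraction of them have basal binding, agonist-
    only binding, or none; optionally the fraction DE in the knockout."""
    if motif_id not in occ.presence.columns:
        raise DataError(f"motif {motif_id!r} absent from occurrence matrix")
    gain = top_n(ranked, n_top, "gain")
    with_motif = [p for p in gain
                  if p in occ.presence.index and occ.presence.loc[p, motif_id]]
    report: dict = {"motif": motif_id, "n_top_gain": n_top,
                    "n_gain_peaks_with_motif": len(with_motif)}
    if not with_motif:
        report["note"] = "no gain peaks carry the motif; fractions undefined"
        return report
    genes = sorted(set(annotations.loc[with_motif, "nearest_gene"].dropna()))
    report["genes"] = genes
    evid = pd.Series({g: binding.evidence(g) for g in genes})
    n = len(genes)
    report["fraction_basal_bound"] = float((evid == "basal").sum() / n)
    report["fraction_agonist_only"] = float((evid == "agonist-only").sum() / n)
    report["fraction_unbound"] = float((evid == "none").sum() / n)
    if ko_classes is not None:
        de = ko_classes.reindex(genes).isin(["up", "down"])
        report["fraction_de_in_ko"] = float(de.mean())
    return report


def tf_expression_report(de: DETable, tf_gene_ids: list[str],
                         alpha: float = 0.05) -> pd.DataFrame:
    """Verbatim DE lookup for a list of TF genes, with class labels;
    missing genes are listed as untested."""
    classes = classify_de(de, alpha)
    rows = []
    for gid in tf_gene_ids:
        if gid in de.table.index:
            rows.append({"gene_id": gid,
                         "log2_fold_change": float(de.table.loc[gid, "log2_fold_change"]),
                         "adjusted_p": float(de.table.loc[gid, "adjusted_p"]),
                         "class": classes[gid]})
        else:
            rows.append({"gene_id": gid, "log2_fold_change": np.nan,
                         "adjusted_p": np.nan, "class": "untested"})
    return pd.DataFrame(rows).set_index("gene_id")
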