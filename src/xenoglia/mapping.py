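"""Cross-dataset cell-state mapping by correlation of DE signatures.

A cluster's signature is the vector of log fold changes of its
differentially expressed genes. Reference signatures keep genes passing
both a P cutoff and a logFC magnitude cutoff; query signatures use the P
cutoff only. Mouse signatures are moved onto human identifiers through an
ortholog table with conservative tie-breaking (one-to-many resolved by the
highest logFC in the human reference, many-to-one by the highest mouse
logFC). Reference and query are then compared pairwise by Pearson
correlation over shared genes, with Benjamini-Hochberg adjustment across
the whole map and optional masking of non-positive correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix


@dataclass
class SignatureVector:
    """Gene -> logFC map for one (dataset, cluster) source."""

    source: str
    logfc: pd.Series
    filters: dict = field(default_factory=dict)


def build_signature(
    de: pd.DataFrame,
    source: str = "",
    logfc_cut: float = 0.25,
    p_cut: float = 0.05,
    apply_logfc_cut: bool = True,
    p_column: str = "p",
) -> SignatureVector:
    """Signature from a DE table: genes with p < p_cut (and, when
    ``apply_logfc_cut`` is set, |logFC| >= logfc_cut) mapped to their logFC."""
    keep = de[p_column] < p_cut
    if apply_logfc_cut:
        keep &= de["log2FC"].abs() >= logfc_cut
    sub = de.loc[keep]
    if len(sub) == 0:
        warnings.warn(f"signature {source!r} is empty after filtering")
    return SignatureVector(
        source=source,
        logfc=pd.Series(sub["log2FC"].to_numpy(), index=pd.Index(sub["gene"])),
        filters={
            "p_cut": p_cut,
            "logfc_cut": logfc_cut if apply_logfc_cut else None,
            "p_column": p_column,
        },
    )


def convert_orthologs(
    mouse_sig: SignatureVector,
    table: pd.DataFrame,
    human_ref: pd.DataFrame,
) -> tuple[SignatureVector, pd.DataFrame]:
    """Move a mouse signature onto human gene identifiers.

    For a mouse gene with several human orthologs, the human gene with the
    highest logFC in ``human_ref`` is chosen (genes absent from the
    reference rank lowest). When several mouse genes resolve to the same
    human gene, the mouse gene with the highest logFC in the signature
    wins. Unmapped mouse genes are dropped. Returns the converted
    signature and a ledger recording every decision; the result is
    independent of the row order of the table.
    """
    if len(table) == 0:
        warnings.warn("empty ortholog table; signature converts to empty")
        return (
            SignatureVector(mouse_sig.source, pd.Series(dtype=float), mouse_sig.filters),
            pd.DataFrame(columns=["mouse_gene", "human_gene", "decision"]),
        )
    href = pd.Series(
        human_ref["log2FC"].to_numpy(), index=pd.Index(human_ref["gene"])
    )
    pairs = table[["mouse_gene", "human_gene"]].drop_duplicates()
    ledger = []
    chosen = {}  # mouse_gene -> human_gene
    for mg in mouse_sig.logfc.index:
        cands = pairs.loc[pairs["mouse_gene"] == mg, "human_gene"]
        if len(cands) == 0:
            ledger.append((mg, None, "unmapped_dropped"))
            continue
        # rank candidates by human-reference logFC; absent genes lowest,
        # name as the deterministic tie-break
        ranked = sorted(
            cands,
            key=lambda h: (href.get(h, -np.inf), h),
            reverse=True,
        )
        chosen[mg] = ranked[0]
        decision = "one_to_one" if len(cands) == 1 else "one_to_many_resolved"
        ledger.append((mg, ranked[0], decision))

    # many-to-one: keep the mouse gene with the highest signature logFC
    out = {}
    by_human: dict[str, list] = {}
    for mg, hg in chosen.items():
        by_human.setdefault(hg, []).append(mg)
    for hg, mgs in by_human.items():
        winner = max(mgs, key=lambda m: (mouse_sig.logfc[m], m))
        out[hg] = mouse_sig.logfc[winner]
        for m in mgs:
            if m != winner:
                ledger.append((m, hg, "many_to_one_lost"))

    ledger_df = pd.DataFrame(ledger, columns=["mouse_gene", "human_gene", "decision"])
    converted = SignatureVector(
        source=mouse_sig.source,
        logfc=pd.Series(out).sort_index(),
        filters=dict(mouse_sig.filters, orthologs="converted"),
    )
    return converted, ledger_df


def correlate_signatures(
    ref_sigs: list[SignatureVector],
    query_sigs: list[SignatureVector],
    min_shared: int = 10,
    positive_only: bool = False,
    method: str = "bh",
) -> pd.DataFrame:
    """Pairwise Pearson correlation of reference and query logFC vectors.

    For every (reference state, query cluster) pair the gene sets are
    intersected; pairs sharing at least ``min_shared`` genes get a Pearson
    r and a t-transform p-value on n - 2 degrees of freedom. Adjusted p
    values are computed jointly across all cells of the map
    (Benjamini-Hochberg by default, ``method="bonferroni"`` as the
    alternative). With ``positive_only``, cells with r <= 0 get a masked
    presentation column ``r_shown``; r and p are retained.
    """
    rows = []
    for ref in ref_sigs:
        for q in query_sigs:
            shared = ref.logfc.index.intersection(q.logfc.index)
            if len(shared) < min_shared:
                rows.append((ref.source, q.source, np.nan, np.nan, len(shared)))
                continue
            x = ref.logfc[shared].to_numpy()
            y = q.logfc[shared].to_numpy()
            r, p = stats.pearsonr(x, y)
            rows.append((ref.source, q.source, r, p, len(shared)))
    cmap = pd.DataFrame(rows, columns=["ref_state", "query_cluster", "r", "p", "n_genes"])
    ok = cmap["p"].notna()
    cmap["p_adj"] = np.nan
    if ok.any():
        cmap.loc[ok, "p_adj"] = multipletests(
            cmap.loc[ok, "p"], method="fdr_bh" if method == "bh" else "bonferroni"
        )[1]
    cmap["r_shown"] = cmap["r"].where(cmap["r"] > 0) if positive_only else cmap["r"]
    return cmap


def signature_overlap_pct(set_a, set_b) -> dict:
    """Percent of set A found in set B, plus the Jaccard index."""
    a, b = set(set_a), set(set_b)
    if not a:
        raise ValueError("set A must be nonempty")
    inter = a & b
    return {
        "pct_a_in_b": 100.0 * len(inter) / len(a),
        "jaccard": len(inter) / len(a | b) if (a | b) else 0.0,
        "n_shared": len(inter),
    }


def risk_gene_report(
    counts: CountMatrix,
    contrasts: dict[str, pd.DataFrame],
    panel: list[str],
    p_adj_cut: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Detection counts and per-contrast logFC profile for a gene panel.

    Panel genes are matched case-insensitively against the matrix. Each row
    reports the number of cells with >= 1 raw read and, per contrast, the
    log2FC where the adjusted p passes ``p_adj_cut`` (masked to NaN
    otherwise). Rows are ordered by average-linkage hierarchical clustering
    of the logFC profile (Euclidean, masked entries treated as 0). Returns
    the report and the list of panel genes not found in the matrix.
    """
    lower_map = {}
    for g in counts.genes:
        lower_map.setdefault(g.lower(), g)
    matched, missing = {}, []
    for g in panel:
        hit = lower_map.get(g.lower())
        if hit is None:
            missing.append(g)
        else:
            matched[g] = hit

    rows = {}
    m = counts.matrix.tocsr()
    gene_pos = {g: i for i, g in enumerate(counts.genes)}
    for g in panel:
        if g in matched:
            n_det = int((m[gene_pos[matched[g]]] > 0).sum())
        else:
            n_det = 0
        row = {"n_cells_detected": n_det}
        for name, de in contrasts.items():
            sub = de.loc[
                (de["gene"].str.lower() == g.lower()) & (de["p_adj"] < p_adj_cut)
            ]
            row[name] = sub["log2FC"].iloc[0] if len(sub) else np.nan
        rows[g] = row
    report = pd.DataFrame(rows).T
    report.index.name = "gene"

    profile = report.drop(columns="n_cells_detected").fillna(0.0).to_numpy(dtype=float)
    if len(report) > 2 and profile.shape[1] >= 1:
        order = sch.leaves_list(sch.linkage(profile, method="average", metric="euclidean"))
        report = report.iloc[order]
    return report, missing
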