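"""Polycomb binding-domain gene filter.

A gene passes when it has significant Dam-Pc occupancy in control,
significant Dam-Pol II occupancy in both genotypes, and its gene-level
Dam-Pc occupancy (on the SD-scaled, replicate-averaged track) is above 1
in control and below 1 in the knockdown.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .fragments import FragmentAssignment
from .tracks import RatioTrack

PC_FILTER_COLUMNS = [
    "gene_id",
    "pc_occ_control",
    "pc_occ_knockdown",
    "pc_significant_control",
    "polII_significant_control",
    "polII_significant_knockdown",
    "passes",
]


def pc_gene_occupancy(
    scaled_avg_pc_track: RatioTrack, assignment: FragmentAssignment
) -> pd.Series:
    """Gene-level length-weighted mean of a scaled, averaged Dam-Pc track.

    The 1.0 pass/fail threshold is defined on the SD-scaled axis, so an
    unscaled input is a hard error.
    """
    if not scaled_avg_pc_track.scaled:
        raise ValueError("Pc occupancy threshold requires an SD-scaled track")
    lens = scaled_avg_pc_track.fmap.lengths.astype(np.float64)
    vals = scaled_avg_pc_track.values
    occ = {}
    for gene_id in assignment.gene_ids():
        idx = assignment.gene_fragments(gene_id)
        w = lens[idx]
        occ[gene_id] = float(np.sum(w * vals[idx]) / np.sum(w))
    return pd.Series(occ, name="pc_occupancy").sort_index()


def pc_loss_filter(
    pc_ctl_occ: pd.Series,
    pc_kd_occ: pd.Series,
    pc_sig_ctl: set[str],
    polII_ctl: pd.DataFrame,
    polII_kd: pd.DataFrame,
) -> pd.DataFrame:
    """One PcFilterRecord row per gene, sorted by control Pc occupancy
    (descending).

    ``polII_*`` are gene occupancy tables with ``gene_id`` and
    ``significant`` columns.  Gene universes must agree between the two
    occupancy series.
    """
    genes_ctl = set(pc_ctl_occ.index)
    genes_kd = set(pc_kd_occ.index)
    if genes_ctl != genes_kd:
        offenders = sorted(genes_ctl.symmetric_difference(genes_kd))
        raise ValueError(f"gene-id mismatch across Pc inputs: {offenders}")
    sig_ctl = _sig_genes(polII_ctl)
    sig_kd = _sig_genes(polII_kd)
    rows = []
    for gene_id in sorted(genes_ctl):
        occ_ctl = float(pc_ctl_occ[gene_id])
        occ_kd = float(pc_kd_occ[gene_id])
        pc_sig = gene_id in pc_sig_ctl
        p2_ctl = gene_id in sig_ctl
        p2_kd = gene_id in sig_kd
        rows.append(
            {
                "gene_id": gene_id,
                "pc_occ_control": occ_ctl,
                "pc_occ_knockdown": occ_kd,
                "pc_significant_control": pc_sig,
                "polII_significant_control": p2_ctl,
                "polII_significant_knockdown": p2_kd,
                "passes": pc_sig and p2_ctl and p2_kd
                and occ_ctl > 1.0 and occ_kd < 1.0,
            }
        )
    out = pd.DataFrame(rows, columns=PC_FILTER_COLUMNS)
    return out.sort_values(
        "pc_occ_control", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def _sig_genes(gene_table: pd.DataFrame) -> set[str]:
    if gene_table.empty:
        return set()
    return set(gene_table.loc[gene_table["significant"], "gene_id"])


def mean_pc_binding(
    gene_set: list[str],
    scaled_avg_pc_track: RatioTrack,
    assignment: FragmentAssignment,
) -> pd.DataFrame:
    """Per-gene mean Pc binding for a gene set, ranked high to low."""
    if not gene_set:
        warnings.warn("empty gene set: no Pc binding to report")
        return pd.DataFrame(columns=["gene_id", "mean_pc_binding"])
    occ = pc_gene_occupancy(scaled_avg_pc_track, assignment)
    missing = [g for g in gene_set if g not in occ.index]
    if missing:
        raise KeyError(f"genes absent from assignment: {missing}")
    out = pd.DataFrame(
        {"gene_id": list(gene_set), "mean_pc_binding": [occ[g] for g in gene_set]}
    )
    return out.sort_values(
        "mean_pc_binding", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
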