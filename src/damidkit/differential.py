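"""Differential Pol II occupancy between genotypes.

Replicate log2-ratio tracks are subtracted pairwise (knockdown minus
control, paired by replicate index), averaged, and the averaged difference
track is fed through the permutation occupancy machinery twice: once for
enrichment (up) and once for depletion (down), with Benjamini-Hochberg
within each direction.  Up-genes must additionally be Pol II-bound in the
knockdown (numerator) dataset; down-genes must clear a fold-change
threshold on the locus-average delta.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fragments import FragmentAssignment
from .occupancy import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_FRAGMENTS,
    gene_table_from_transcripts,
    occupancy_significance,
)
from .tracks import RatioTrack, average_tracks

DEFAULT_FC_THRESHOLD = 1.3

DIFFERENTIAL_COLUMNS = [
    "gene_id",
    "locus_delta",
    "direction",
    "fdr",
    "bound_in_numerator",
    "passes_fc",
    "in_up_list",
    "in_down_list",
    "exclusion_reason",
]


def difference_tracks(
    knockdown_reps: list[RatioTrack], control_reps: list[RatioTrack]
) -> list[RatioTrack]:
    """Fragment-wise knockdown minus control, paired by replicate index."""
    if len(knockdown_reps) != len(control_reps):
        raise ValueError(
            "replicate counts differ between genotypes; pairing is undefined"
        )
    if not knockdown_reps:
        raise ValueError("no replicates")
    diffs = []
    for kd, ctl in zip(knockdown_reps, control_reps):
        if not kd.fmap.same_map(ctl.fmap):
            raise ValueError("mismatched fragment maps between genotypes")
        if kd.scaled or ctl.scaled:
            raise ValueError("difference tracks are defined on unscaled ratios")
        diffs.append(
            RatioTrack(
                kd.fmap,
                kd.values - ctl.values,
                sample_kind="difference",
                genotype=f"{kd.genotype}-minus-{ctl.genotype}",
                replicate=kd.replicate,
            )
        )
    return diffs


def locus_average_ratio(
    averaged_diff_track: RatioTrack, gene_id: str, assignment: FragmentAssignment
) -> float:
    """Length-weighted mean of the averaged difference track over the union
    of the gene's transcript fragments."""
    idx = assignment.gene_fragments(gene_id)  # KeyError if absent
    w = averaged_diff_track.fmap.lengths[idx].astype(np.float64)
    return float(np.sum(w * averaged_diff_track.values[idx]) / np.sum(w))


def isoform_ratios(
    averaged_diff_track: RatioTrack, assignment: FragmentAssignment
) -> pd.DataFrame:
    """Per-transcript length-weighted delta, for best-isoform reporting."""
    lens = averaged_diff_track.fmap.lengths.astype(np.float64)
    vals = averaged_diff_track.values
    rows = [
        {
            "transcript_id": tid,
            "gene_id": assignment.transcript_gene[tid],
            "delta": float(np.sum(lens[idx] * vals[idx]) / np.sum(lens[idx])),
        }
        for tid, idx in assignment.transcript_fragments.items()
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "delta"])


def differential_genes(
    diff_tracks: list[RatioTrack],
    assignment: FragmentAssignment,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    numerator_gene_table: pd.DataFrame | None = None,
    numerator_genotype: str | None = None,
    min_fragments: int = DEFAULT_MIN_FRAGMENTS,
) -> pd.DataFrame:
    """Call genes with changed occupancy from replicate difference tracks.

    ``numerator_gene_table`` is the knockdown genotype's own Pol II gene
    occupancy table (with a ``significant`` column); its ``attrs['genotype']``,
    when present, must match ``numerator_genotype``.
    """
    if numerator_gene_table is None:
        raise ValueError("a numerator (knockdown Pol II) gene table is required")
    table_genotype = numerator_gene_table.attrs.get("genotype")
    if (
        numerator_genotype is not None
        and table_genotype is not None
        and table_genotype != numerator_genotype
    ):
        raise ValueError(
            f"numerator table is for genotype {table_genotype!r}, "
            f"expected {numerator_genotype!r}"
        )

    avg = average_tracks(diff_tracks)
    up_tx = occupancy_significance(
        avg, assignment, n_perm, seed, alpha, min_fragments, alternative="greater"
    )
    down_tx = occupancy_significance(
        avg, assignment, n_perm, seed, alpha, min_fragments, alternative="less"
    )
    up_genes = gene_table_from_transcripts(up_tx).set_index("gene_id")
    down_genes = gene_table_from_transcripts(down_tx).set_index("gene_id")

    numerator_sig = set(
        numerator_gene_table.loc[numerator_gene_table["significant"], "gene_id"]
    )
    log2_fc = np.log2(fc_threshold)

    rows = []
    for gene_id in up_genes.index:
        delta = locus_average_ratio(avg, gene_id, assignment)
        direction = "up" if delta > 0 else "down"
        fdr = float(
            (up_genes if direction == "up" else down_genes).loc[gene_id, "fdr"]
        )
        bound = gene_id in numerator_sig
        passes_fc = bool(abs(delta) > log2_fc)
        reason = ""
        if direction == "up":
            in_up = fdr < alpha and bound
            in_down = False
            if fdr < alpha and not bound:
                reason = "not Pol II-bound in numerator dataset"
        else:
            in_up = False
            in_down = fdr < alpha and passes_fc
            if fdr < alpha and not passes_fc:
                reason = f"fold-change below {fc_threshold}"
        rows.append(
            {
                "gene_id": gene_id,
                "locus_delta": delta,
                "direction": direction,
                "fdr": fdr,
                "bound_in_numerator": bound,
                "passes_fc": passes_fc,
                "in_up_list": in_up,
                "in_down_list": in_down,
                "exclusion_reason": reason,
            }
        )
    out = pd.DataFrame(rows, columns=DIFFERENTIAL_COLUMNS)
    out = out.sort_values(["fdr", "gene_id"], kind="mergesort").reset_index(drop=True)
    out.attrs["fc_threshold"] = fc_threshold
    out.attrs["alpha"] = alpha
    return out
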