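"""Per-fragment log2(Dam-fusion / Dam) ratio tracks.

Count vectors are equalized to reads-per-million before the ratio, and a
pseudocount (applied after scaling, so the zero-count floor is
depth-independent) keeps every value finite.  Replicate tracks can be
scaled to unit population standard deviation and averaged, mirroring the
standard DamID profile-building convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fragments import FragmentMap

DEFAULT_PSEUDOCOUNT = 0.5
_RPM = 1e6


@dataclass
class RatioTrack:
    fmap: FragmentMap
    values: np.ndarray
    sample_kind: str | None = None  # "Dam-PolII" | "Dam-Pc" | derived
    genotype: str | None = None
    replicate: int | tuple | None = None
    scaled: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.fmap.n_fragments,):
            raise ValueError("track length does not match fragment map")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track contains non-finite values")

    def with_values(self, values: np.ndarray, **meta) -> "RatioTrack":
        out = replace(self, values=np.asarray(values, dtype=np.float64))
        for k, v in meta.items():
            setattr(out, k, v)
        return out


def _check_same_map(a: RatioTrack, b: RatioTrack) -> None:
    if not a.fmap.same_map(b.fmap):
        raise ValueError("tracks are on different fragment maps")


def compute_ratio_track(
    fusion_counts: np.ndarray,
    dam_counts: np.ndarray,
    fmap: FragmentMap,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    sample_kind: str | None = None,
    genotype: str | None = None,
    replicate: int | None = None,
) -> RatioTrack:
    """log2((fusion_i * s_f + pc) / (dam_i * s_d + pc)) with RPM scale factors.

    Invariant to rescaling either sample's counts by a positive constant.
    """
    fusion = np.asarray(fusion_counts, dtype=np.float64)
    dam = np.asarray(dam_counts, dtype=np.float64)
    if fusion.shape != (fmap.n_fragments,) or dam.shape != (fmap.n_fragments,):
        raise ValueError("count vectors do not match the fragment map")
    if np.any(fusion < 0) or np.any(dam < 0):
        raise ValueError("negative counts")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    tf, td = fusion.sum(), dam.sum()
    if tf <= 0 or td <= 0:
        raise ValueError("each sample must have positive total counts")
    values = np.log2(fusion * (_RPM / tf) + pseudocount) - np.log2(
        dam * (_RPM / td) + pseudocount
    )
    return RatioTrack(fmap, values, sample_kind, genotype, replicate)


def replicate_correlation(track_a: RatioTrack, track_b: RatioTrack) -> float:
    """Unweighted Pearson r over per-fragment values."""
    _check_same_map(track_a, track_b)
    if track_a.fmap.n_fragments < 3:
        raise ValueError("need at least 3 fragments for a correlation")
    if np.std(track_a.values) == 0 or np.std(track_b.values) == 0:
        raise ValueError("correlation undefined for a zero-variance track")
    return float(np.corrcoef(track_a.values, track_b.values)[0, 1])


def scale_by_sd(track: RatioTrack) -> RatioTrack:
    """Divide all values by their population standard deviation (unweighted)."""
    sd = float(np.std(track.values))  # ddof=0
    if sd == 0:
        raise ValueError("cannot scale a zero-variance track")
    return track.with_values(track.values / sd, scaled=True)


def average_tracks(tracks: list[RatioTrack]) -> RatioTrack:
    """Fragment-wise arithmetic mean of replicate tracks."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        _check_same_map(first, t)
        if t.scaled != first.scaled:
            raise ValueError("cannot mix scaled and unscaled tracks")
    mean = np.mean(np.stack([t.values for t in tracks]), axis=0)
    return RatioTrack(
        first.fmap,
        mean,
        sample_kind=first.sample_kind,
        genotype=first.genotype,
        replicate=tuple(t.replicate for t in tracks),
        scaled=first.scaled,
    )


def write_bedgraph(track: RatioTrack, path) -> None:
    with open(path, "w") as fh:
        for i in range(track.fmap.n_fragments):
            chrom = track.fmap.chrom_names[track.fmap.chrom_index[i]]
            fh.write(
                f"{chrom}\t{track.fmap.starts[i]}\t{track.fmap.ends[i]}\t"
                f"{track.values[i]:.6g}\n"
            )


def read_bedgraph(path, fmap: FragmentMap, **meta) -> RatioTrack:
    """Read a bedgraph whose intervals must exactly match ``fmap``."""
    values = np.empty(fmap.n_fragments, dtype=np.float64)
    i = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            if i >= fmap.n_fragments:
                raise ValueError("bedgraph has more intervals than the fragment map")
            expect = fmap.chrom_names[fmap.chrom_index[i]]
            if chrom != expect or int(s) != fmap.starts[i] or int(e) != fmap.ends[i]:
                raise ValueError(f"bedgraph interval {i} does not match fragment map")
            values[i] = float(v)
            i += 1
    if i != fmap.n_fragments:
        raise ValueError("bedgraph has fewer intervals than the fragment map")
    return RatioTrack(fmap, values, **meta)
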