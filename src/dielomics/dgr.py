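"""Diversity-generating retroelement (DGR) adenine-hypermutation analysis.

A DGR copies a template repeat (TR) into one or more variable repeats (VR)
through error-prone reverse transcription that substitutes specifically at
TR adenine positions.  Given a per-site base-count pileup from resequencing,
this module maps TR adenines onto VR coordinates, computes per-site
nucleotide diversity (pi — the probability that two randomly drawn reads
differ at a site, unbiased pairwise form with denominator C(n, 2)), and
tests whether diversity is elevated at adenine-aligned sites with a
label-permutation test.

Coordinates are 0-based half-open throughout; pileup base counts are
reference-forward, and reverse-strand VRs are handled through the explicit
TR -> VR alignment map (the adenine test always uses the TR sense strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, InputError

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")
_COUNT_COLS = ("nA", "nC", "nG", "nT")


@dataclass
class VrRegion:
    name: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class DgrLocus:
    """TR sequence plus VR intervals and (optionally gapped) alignment maps.

    ``alignment_maps[vr_name]`` is a list of ``(tr_index, vr_reference_pos)``
    pairs; when absent, an ungapped co-linear map from the VR start is used.
    """

    tr_sequence: str
    tr_interval: tuple[int, int] | None = None
    vr_regions: list[VrRegion] = field(default_factory=list)
    alignment_maps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.tr_sequence) - set(_BASES)
        if bad:
            raise InputError(f"TR has non-ACGT characters: {sorted(bad)}")
        L = len(self.tr_sequence)
        for name, pairs in self.alignment_maps.items():
            vr = self.vr(name)
            for ti, vp in pairs:
                if not 0 <= ti < L:
                    raise InputError(f"alignment map {name}: TR index {ti} out of range")
                if not vr.start <= vp < vr.end:
                    raise InputError(
                        f"alignment map {name}: position {vp} outside VR interval")

    def vr(self, name: str) -> VrRegion:
        for region in self.vr_regions:
            if region.name == name:
                return region
        raise InputError(f"unknown VR region {name!r}")

    def alignment(self, name: str) -> list[tuple[int, int]]:
        if name in self.alignment_maps:
            return list(self.alignment_maps[name])
        vr = self.vr(name)
        return [(i, vr.start + i) for i in range(len(self.tr_sequence))
                if vr.start + i < vr.end]


@dataclass
class PileupTable:
    """Per-reference-position depth and A/C/G/T counts (reference-forward)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["pos", "ref", "depth", *_COUNT_COLS]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise InputError(f"pileup missing columns: {missing}")
        pos = self.table["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise InputError("pileup positions must be strictly increasing")
        counts = self.table[list(_COUNT_COLS)].to_numpy()
        if (counts < 0).any():
            raise InputError("negative base counts")
        over = counts.sum(axis=1) > self.table["depth"].to_numpy()
        if over.any():
            bad = self.table["pos"].to_numpy()[over][0]
            raise InputError(f"base counts exceed depth at position {bad}")
        self.table = self.table.set_index("pos", drop=False)

    def counts_at(self, pos: int) -> dict[str, int]:
        row = self.table.loc[pos]
        return {b: int(row[f"n{b}"]) for b in _BASES}


@dataclass
class PiProfile:
    """Per-position pi with depth masking and adenine-alignment flags."""

    region_name: str
    table: pd.DataFrame  # columns: pos, pi (NaN = masked), depth, is_adenine_site

    @property
    def mean_pi(self) -> float:
        return float(self.table["pi"].mean())

    def mean_pi_by_flag(self) -> tuple[float, float]:
        ok = self.table["pi"].notna()
        a = self.table.loc[ok & self.table["is_adenine_site"], "pi"]
        o = self.table.loc[ok & ~self.table["is_adenine_site"], "pi"]
        return float(a.mean()) if len(a) else float("nan"), \
            float(o.mean()) if len(o) else float("nan")


@dataclass
class AdenineContrast:
    delta: float
    perm_p: float
    n_perm: int
    seed: int
    n_adenine: int
    n_other: int


def adenine_positions(locus: DgrLocus, vr_name: str) -> set[int]:
    """VR reference positions whose aligned TR base is adenine (TR sense).

    TR adenines that fall in an alignment gap are excluded and counted in a
    log message.
    """
    pairs = dict(locus.alignment(vr_name))
    a_idx = [i for i, b in enumerate(locus.tr_sequence) if b == "A"]
    mapped = {pairs[i] for i in a_idx if i in pairs}
    unmapped = sum(1 for i in a_idx if i not in pairs)
    if unmapped:
        logger.info("VR %s: %d TR adenines unmapped (alignment gaps)",
                    vr_name, unmapped)
    return mapped


def site_pi(counts: dict[str, int] | np.ndarray) -> float:
    """Per-site nucleotide diversity, pairwise form.

    pi = sum_{b < b'} n_b n_b' / C(n, 2); returns NaN (masked) when the
    usable depth n = nA+nC+nG+nT is below 2.
    """
    if isinstance(counts, dict):
        c = np.array([counts.get(b, 0) for b in _BASES], dtype=float)
    else:
        c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 2:
        return float("nan")
    mismatch_pairs = (n * n - (c * c).sum()) / 2.0
    return float(mismatch_pairs / (n * (n - 1) / 2.0))


def _vector_pi(counts: np.ndarray) -> np.ndarray:
    n = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = (n * n - (counts * counts).sum(axis=1)) / (n * (n - 1))
    pi[n < 2] = np.nan
    return pi


def pi_profile(
    pileup: PileupTable,
    region: tuple[int, int],
    locus: DgrLocus,
    vr_name: str | None = None,
    min_depth: int = 10,
    region_name: str | None = None,
) -> PiProfile:
    """Per-position pi over ``region`` with depth masking and adenine flags.

    For a VR, ``vr_name`` selects the alignment used to flag adenine-aligned
    positions; for the TR region itself the flags come directly from the TR
    sequence.
    """
    start, end = region
    sub = pileup.table[(pileup.table["pos"] >= start) & (pileup.table["pos"] < end)]
    if sub.empty:
        raise InputError(f"pileup has no positions in [{start}, {end})")
    counts = sub[list(_COUNT_COLS)].to_numpy(dtype=float)
    pi = _vector_pi(counts)
    usable = counts.sum(axis=1)
    pi[usable < min_depth] = np.nan
    if vr_name is not None:
        a_sites = adenine_positions(locus, vr_name)
        name = region_name or vr_name
    else:
        a_sites = {start + i for i, b in enumerate(locus.tr_sequence) if b == "A"}
        name = region_name or "TR"
    table = pd.DataFrame({
        "pos": sub["pos"].to_numpy(),
        "pi": pi,
        "depth": sub["depth"].to_numpy(),
        "is_adenine_site": [p in a_sites for p in sub["pos"]],
    })
    if table["pi"].notna().sum() == 0:
        raise InputError(f"region {name}: every position masked (min_depth={min_depth})")
    return PiProfile(region_name=name, table=table)


def adenine_contrast(
    profile: PiProfile,
    n_perm: int = 10000,
    seed: int = 0,
) -> AdenineContrast:
    """Permutation test for elevated pi at adenine-aligned sites.

    delta = mean(pi | adenine) - mean(pi | other); the null shuffles the
    adenine flags over unmasked positions, perm_p = (1 + #{delta* >= delta})
    / (1 + n_perm).
    """
    ok = profile.table["pi"].notna().to_numpy()
    pi = profile.table["pi"].to_numpy()[ok]
    flags = profile.table["is_adenine_site"].to_numpy()[ok]
    n_a = int(flags.sum())
    n_o = int((~flags).sum())
    if n_a < 2 or n_o < 2:
        raise DesignError(
            f"adenine contrast needs >=2 sites per group (got {n_a} adenine, {n_o} other)")
    delta = float(pi[flags].mean() - pi[~flags].mean())
    rng = np.random.default_rng(seed)
    m = len(pi)
    # vectorized flag shuffles: argsort of uniforms = random permutations
    order = np.argsort(rng.random((n_perm, m)), axis=1)
    perm_flags = np.take_along_axis(
        np.broadcast_to(flags, (n_perm, m)).copy(), order, axis=1)
    sums_a = (pi[np.newaxis, :] * perm_flags).sum(axis=1)
    total = pi.sum()
    deltas = sums_a / n_a - (total - sums_a) / n_o
    exceed = int((deltas >= delta - 1e-15).sum())
    perm_p = (1 + exceed) / (1 + n_perm)
    return AdenineContrast(delta=delta, perm_p=perm_p, n_perm=n_perm, seed=seed,
                           n_adenine=n_a, n_other=n_o)


def compare_vr_tr(
    tr_profile: PiProfile,
    vr_profiles: list[PiProfile],
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Summary table contrasting VR diversity with the TR.

    One row per region (TR first): mean pi overall and split by adenine
    alignment, the adenine-contrast statistics, and the VR - TR differences.
    """
    rows = []
    profiles = [tr_profile, *vr_profiles]
    tr_mean = tr_profile.mean_pi
    tr_a, tr_o = tr_profile.mean_pi_by_flag()
    for prof in profiles:
        mean_a, mean_o = prof.mean_pi_by_flag()
        try:
            ctr = adenine_contrast(prof, n_perm=n_perm, seed=seed)
            delta, perm_p = ctr.delta, ctr.perm_p
        except DesignError:
            delta, perm_p = float("nan"), float("nan")
        rows.append({
            "region": prof.region_name,
            "mean_pi": prof.mean_pi,
            "mean_pi_adenine": mean_a,
            "mean_pi_other": mean_o,
            "adenine_delta": delta,
            "adenine_perm_p": perm_p,
            "diff_mean_pi_vs_tr": prof.mean_pi - tr_mean,
            "diff_adenine_pi_vs_tr": mean_a - tr_a,
        })
    return pd.DataFrame(rows)
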