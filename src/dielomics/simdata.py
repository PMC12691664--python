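"""Synthetic diel transcriptomes and DGR pileups with known ground truth.

The expression generator emulates a 12-time-point x 3-replicate diel design
(12 h light / 12 h dark, two core entrainment cycles plus 24-h constant-light
and constant-dark perturbations and two early time points).  Planted signal
classes:

* ``light_pref`` / ``dark_pref`` genes whose mean is multiplied by
  ``2**effect_log2`` in samples of the preferred phase;
* co-expressed gene blocks sharing a latent per-time-point profile, applied
  multiplicatively as ``exp(loading * profile(t))`` — including a dark-spiking
  "prophage-like" block elevated only at MidDark2;
* ``null`` genes with a flat mean.

Per-gene baselines are log-normal and counts are negative-binomial
(var = mu + dispersion * mu^2).  The DGR generator emits a base-count pileup
over a template repeat (TR) and its variable-repeat (VR) copies in which
population alternate alleles occur only at TR-adenine-aligned positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dgr import DgrLocus, PileupTable, VrRegion
from .errors import ConfigError, InputError
from .preprocess import ExpressionMatrix

# ---------------------------------------------------------------------------
# Diel design constants: 12 time points sampled in triplicate.
# ---------------------------------------------------------------------------

DEFAULT_TIMEPOINTS: tuple[str, ...] = (
    "MidDark1", "Pre-Dawn1", "MidLight1", "Pre-Dusk1",
    "MidDark2", "Pre-Dawn2", "MidLight2", "Pre-Dusk2",
    "Light24", "Dark24", "Pre-Dawn0", "Pre-Dusk0",
)

#: Day = Pre-Dusk / MidLight / Light24; night = Pre-Dawn / MidDark / Dark24.
DEFAULT_PHASES: dict[str, str] = {
    "MidDark1": "dark", "Pre-Dawn1": "dark", "MidLight1": "light",
    "Pre-Dusk1": "light", "MidDark2": "dark", "Pre-Dawn2": "dark",
    "MidLight2": "light", "Pre-Dusk2": "light", "Light24": "light",
    "Dark24": "dark", "Pre-Dawn0": "dark", "Pre-Dusk0": "light",
}

#: The two full entrainment cycles (stages II-III) used for the ANOVA.
CORE_TIMEPOINTS: tuple[str, ...] = DEFAULT_TIMEPOINTS[:8]

#: Collapse the two occurrences of each core time point into a diel state.
CORE_STATE_OF_TIMEPOINT: dict[str, str] = {
    tp: tp.rstrip("012") for tp in CORE_TIMEPOINTS
}

ANOVA_STATES: tuple[str, ...] = ("MidDark", "Pre-Dawn", "MidLight", "Pre-Dusk")


# ---------------------------------------------------------------------------
# Expression simulator
# ---------------------------------------------------------------------------

@dataclass
class ModuleSpec:
    """A planted co-expression block.

    ``profile`` maps time point -> latent value f(t); gene means are
    ``baseline * exp(loading * f(t))``.
    """

    name: str
    size: int
    profile: Mapping[str, float]
    loading: float


def default_module_specs(
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
    phases: Mapping[str, str] = DEFAULT_PHASES,
) -> list[ModuleSpec]:
    """Four planted blocks of 50 genes with distinct latent profiles.

    Three +/-1 profiles at loading 0.7 give within-module Pearson r ~ 0.7
    (for +/-1 f, r = sinh^2(l) / (sinh^2(l) + cosh(2l) * cv^2) with counting
    noise cv^2 ~ 0.1); the fourth is the dark-spiking "prophage-like" block,
    elevated e^2-fold only at MidDark2.
    """
    diel = {tp: (1.0 if phases[tp] == "light" else -1.0) for tp in timepoints}
    early = {tp: (1.0 if tp.endswith(("0", "1")) and tp not in ("Light24", "Dark24")
                  else -1.0) for tp in timepoints}
    transition = {tp: (1.0 if tp.startswith("Pre-") else -1.0) for tp in timepoints}
    spike = {tp: (1.0 if tp == "MidDark2" else 0.0) for tp in timepoints}
    return [
        ModuleSpec("diel", 50, diel, 0.7),
        ModuleSpec("early", 50, early, 0.7),
        ModuleSpec("transition", 50, transition, 0.7),
        ModuleSpec("prophage_spike", 50, spike, 2.0),
    ]


@dataclass
class SimExprConfig:
    """Study-design parameters for the diel expression simulator."""

    n_genes: int = 3000
    timepoint_labels: tuple[str, ...] = DEFAULT_TIMEPOINTS
    phase_of_timepoint: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PHASES))
    n_replicates: int = 3
    frac_light_pref: float = 0.1
    frac_dark_pref: float = 0.1
    effect_log2: float = 1.0
    module_specs: list[ModuleSpec] = field(default_factory=default_module_specs)
    baseline_log_mean: float = math.log(3000.0)
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if not (0 <= self.frac_light_pref and 0 <= self.frac_dark_pref):
            raise ConfigError("class fractions must be non-negative")
        module_genes = sum(m.size for m in self.module_specs)
        total = self.frac_light_pref + self.frac_dark_pref + module_genes / self.n_genes
        if total > 1:
            raise ConfigError(
                f"planted fractions + module sizes exceed n_genes (total {total:.3f})")
        missing = [tp for tp in self.timepoint_labels
                   if tp not in self.phase_of_timepoint]
        if missing:
            raise ConfigError(f"time points without a phase: {missing}")
        for m in self.module_specs:
            missing = [tp for tp in self.timepoint_labels if tp not in m.profile]
            if missing:
                raise ConfigError(f"module {m.name!r} profile missing {missing}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated matrix."""

    gene_class: pd.Series           # gene -> light_pref / dark_pref / module_<name> / null
    module_assignment: pd.Series    # gene -> module name or NaN
    expected_mean: pd.DataFrame     # genes x time points, noise-free means


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + dispersion*mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_diel_counts(config: SimExprConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate a counts matrix plus ground truth for the configured design."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tps = list(config.timepoint_labels)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    n_light = int(round(config.frac_light_pref * n))
    n_dark = int(round(config.frac_dark_pref * n))
    classes = pd.Series("null", index=genes, name="gene_class")
    modules = pd.Series(np.nan, index=genes, dtype=object, name="module")
    pos = 0
    classes.iloc[pos:pos + n_light] = "light_pref"
    pos += n_light
    classes.iloc[pos:pos + n_dark] = "dark_pref"
    pos += n_dark
    for spec in config.module_specs:
        classes.iloc[pos:pos + spec.size] = f"module_{spec.name}"
        modules.iloc[pos:pos + spec.size] = spec.name
        pos += spec.size

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    factor = np.ones((n, len(tps)))
    eff = 2.0 ** config.effect_log2
    for j, tp in enumerate(tps):
        phase = config.phase_of_timepoint[tp]
        cls = classes.to_numpy()
        if phase == "light":
            factor[cls == "light_pref", j] *= eff
        else:
            factor[cls == "dark_pref", j] *= eff
    for spec in config.module_specs:
        rows = (modules == spec.name).to_numpy()
        prof = np.array([spec.profile[tp] for tp in tps])
        factor[rows, :] *= np.exp(spec.loading * prof)[np.newaxis, :]

    expected = baseline[:, np.newaxis] * factor
    sample_ids, meta_rows, columns = [], [], []
    for tp in tps:
        for rep in range(1, config.n_replicates + 1):
            sid = f"{tp}_r{rep}"
            sample_ids.append(sid)
            meta_rows.append((tp, rep, config.phase_of_timepoint[tp]))
            mu = expected[:, tps.index(tp)]
            columns.append(_nb_draw(rng, mu, config.nb_dispersion))
    values = pd.DataFrame(np.column_stack(columns), index=genes,
                          columns=sample_ids, dtype=float)
    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"),
                        columns=["timepoint", "replicate", "phase"])
    truth = SimTruth(
        gene_class=classes,
        module_assignment=modules,
        expected_mean=pd.DataFrame(expected, index=genes, columns=tps),
    )
    return ExpressionMatrix(values, meta), truth


def simulate_gene_sets(
    truth: SimTruth,
    n_random: int = 8,
    set_size: int = 40,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Pathway collection for enrichment tests: one pathway drawn from the
    light-preferential genes, one from the dark-preferential genes, and
    ``n_random`` pathways drawn from the null background."""
    rng = np.random.default_rng(seed)
    cls = truth.gene_class
    sets: dict[str, list[str]] = {}
    for name, label in (("planted_light_pathway", "light_pref"),
                        ("planted_dark_pathway", "dark_pref")):
        pool = cls.index[cls == label].to_list()
        if pool:
            k = min(set_size, len(pool))
            sets[name] = sorted(rng.choice(pool, size=k, replace=False).tolist())
    null_pool = cls.index[cls == "null"].to_list()
    for i in range(n_random):
        k = min(set_size, len(null_pool))
        sets[f"background_pathway_{i + 1}"] = sorted(
            rng.choice(null_pool, size=k, replace=False).tolist())
    return sets


# ---------------------------------------------------------------------------
# DGR pileup simulator
# ---------------------------------------------------------------------------

BASES = ("A", "C", "G", "T")


@dataclass
class DgrSimConfig:
    """Parameters for the DGR resequencing-pileup simulator.

    ``mu_A`` is the population alternate-allele frequency at TR-adenine-aligned
    VR positions: a float for a fixed frequency, or an ``(a, b)`` pair for
    per-site Beta(a, b) frequencies.
    """

    tr_sequence: str
    vr_offsets: tuple[int, ...] = (200,)
    tr_offset: int = 0
    mu_A: float | tuple[float, float] = 0.05
    error_rate: float = 0.002
    depth: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if not self.tr_sequence:
            raise InputError("tr_sequence must be non-empty")
        bad = set(self.tr_sequence) - set(BASES)
        if bad:
            raise InputError(f"tr_sequence has non-ACGT characters: {sorted(bad)}")
        if isinstance(self.mu_A, tuple):
            if any(v <= 0 for v in self.mu_A):
                raise ConfigError("Beta parameters for mu_A must be positive")
        elif not 0 <= self.mu_A <= 1:
            raise ConfigError("mu_A must be in [0, 1]")
        if not 0 <= self.error_rate < 0.1:
            raise ConfigError("error_rate must be in [0, 0.1)")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        L = len(self.tr_sequence)
        regions = [(self.tr_offset, self.tr_offset + L)]
        regions += [(o, o + L) for o in self.vr_offsets]
        regions.sort()
        for (a0, a1), (b0, b1) in zip(regions, regions[1:]):
            if b0 < a1:
                raise ConfigError("TR/VR regions overlap on the reference")


def random_tr_sequence(length: int = 120, n_adenines: int = 30, seed: int = 0) -> str:
    """A TR with exactly ``n_adenines`` A's at random positions."""
    if n_adenines > length:
        raise ConfigError("more adenines than positions")
    rng = np.random.default_rng(seed)
    seq = rng.choice(["C", "G", "T"], size=length)
    a_pos = rng.choice(length, size=n_adenines, replace=False)
    seq[a_pos] = "A"
    return "".join(seq)


def simulate_dgr_pileup(
    config: DgrSimConfig,
) -> tuple[DgrLocus, PileupTable, pd.Series]:
    """Simulate base-count pileups over the TR and its VR copies.

    Sequencing error perturbs every position; at adenine-aligned VR positions
    the population additionally carries an alternate base at frequency
    ``mu_A``.  Returns the locus description, the pileup, and the per-position
    true alternate-allele frequency.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tr = config.tr_sequence
    L = len(tr)
    regions = [VrRegion(f"VR{i + 1}", off, off + L, "+")
               for i, off in enumerate(config.vr_offsets)]
    locus = DgrLocus(tr_sequence=tr, tr_interval=(config.tr_offset, config.tr_offset + L),
                     vr_regions=regions)

    rows = []
    truth: dict[int, float] = {}
    e = config.error_rate

    def emit(start: int, mutated: bool) -> None:
        for j in range(L):
            ref = tr[j]
            pos = start + j
            q = 0.0
            if mutated and ref == "A":
                if isinstance(config.mu_A, tuple):
                    q = float(rng.beta(*config.mu_A))
                else:
                    q = float(config.mu_A)
            truth[pos] = q
            alt = None
            if q > 0:
                alt = rng.choice([b for b in BASES if b != ref])
            depth = max(1, int(rng.poisson(config.depth)))
            p = np.full(4, 0.0)
            ri = BASES.index(ref)
            p[ri] = 1.0 - q
            if alt is not None:
                p[BASES.index(alt)] += q
            # uniform sequencing error to each of the other three bases
            p = p * (1 - e) + (1 - p) * (e / 3)
            counts = rng.multinomial(depth, p / p.sum())
            rows.append((pos, ref, depth, *counts))

    emit(config.tr_offset, mutated=False)
    for region in regions:
        emit(region.start, mutated=True)

    rows.sort(key=lambda r: r[0])
    table = pd.DataFrame(rows, columns=["pos", "ref", "depth", "nA", "nC", "nG", "nT"])
    pileup = PileupTable(table)
    truth_s = pd.Series(truth, name="true_alt_freq").sort_index()
    return locus, pileup, truth_s
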