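"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the five input kinds the workflow consumes —
compound->target assertion tables (multi-database exports), disease
target lists, confidence-scored PPI edge tables, GMT annotation sets,
and oral-dose plasma concentration-time profiles — with the statistical
structure the downstream analysis assumes, so planted quantities
(overlap sizes, clique memberships, PK parameters) can be recovered
exactly or to known tolerance.

Bookkeeping is explicit: the gene universe is partitioned into a
compound-only pool, a disease-only pool and a planted shared pool, so
the consensus intersection downstream equals ``planted_overlap`` by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOURCE_TAGS = ("drugbank", "swisstarget", "sea")

#: Post-dose blood sampling schedule (minutes) of the rat PK study design
#: this generator emulates: dense early sampling through absorption, then
#: sparse sampling out to 24 h.
DEFAULT_SAMPLE_TIMES = (5, 10, 20, 40, 60, 90, 120, 180, 240, 360, 480, 720, 1440)

#: Fraction of compound-target rows duplicated under a second source tag,
#: exercising cross-database deduplication downstream.
DUPLICATE_ASSERTION_RATE = 0.03


@dataclass(frozen=True)
class SyntheticSpec:
    """Sizes and rates for the target-fishing / network inputs.

    Defaults mirror the scale of a 29-component herbal-formula study:
    ~1,200-1,300 putative compound targets, 812 disease targets and a
    planted consensus of 120.
    """

    n_compounds: int = 29
    n_targets_universe: int = 3000
    targets_per_compound: float = 60.0  # Poisson mean
    n_disease_targets: int = 812
    planted_overlap: int = 120
    #: Sampling weight of planted (shared) symbols relative to
    #: compound-pool symbols: consensus disease targets are promiscuous,
    #: recurring across components, which is what gives real C-T
    #: networks their density (~15 consensus targets per compound here).
    planted_weight: float = 6.0
    #: A planted dense bipartite block: a family of chemically similar
    #: components that all bind the same panel of consensus targets
    #: (e.g. one saponin scaffold hitting one transporter/CYP panel).
    #: This is the kind of structure MCODE's top cluster captures in
    #: real compound-target networks.  Sizes are clamped to the spec
    #: and 0 disables the block.
    dense_block_compounds: int = 9
    dense_block_targets: int = 8
    ppi_density: float = 0.1
    score_range: tuple[float, float] = (0.4, 1.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if self.planted_overlap < 0 or self.planted_overlap > self.n_disease_targets:
            raise ValueError("planted_overlap must be in [0, n_disease_targets]")
        if self.n_disease_targets + 1 > self.n_targets_universe:
            # at least one non-disease symbol must exist for compounds
            raise ValueError("universe too small for the requested disease list")
        if self.targets_per_compound <= 0:
            raise ValueError("targets_per_compound must be positive")
        if self.planted_weight <= 0:
            raise ValueError("planted_weight must be positive")
        if self.dense_block_compounds < 0 or self.dense_block_targets < 0:
            raise ValueError("dense block sizes must be >= 0")
        if not 0.0 <= self.ppi_density <= 1.0:
            raise ValueError("ppi_density must be in [0,1]")
        lo, hi = self.score_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("score_range must be ordered and within [0,1]")


def universe_symbols(spec: SyntheticSpec) -> list[str]:
    """The full synthetic gene universe, ``G0001`` .. ``G{n}`` (zero-padded)."""
    width = max(4, len(str(spec.n_targets_universe)))
    return [f"G{i:0{width}d}" for i in range(1, spec.n_targets_universe + 1)]


def _pools(spec: SyntheticSpec):
    """Deterministic partition of the universe into (planted, disease-only, compound pool)."""
    rng = np.random.default_rng([spec.rng_seed, 0])
    symbols = np.array(universe_symbols(spec))
    order = rng.permutation(len(symbols))
    shuffled = symbols[order]
    po = spec.planted_overlap
    nd = spec.n_disease_targets
    planted = frozenset(shuffled[:po])
    disease_only = frozenset(shuffled[po:nd])
    compound_pool = list(shuffled[nd:])
    return planted, disease_only, compound_pool


def planted_symbols(spec: SyntheticSpec) -> frozenset[str]:
    """The symbols forced into both the compound-target union and the disease list."""
    return _pools(spec)[0]


def compound_ids(spec: SyntheticSpec) -> list[str]:
    return [f"C{i:02d}" for i in range(1, spec.n_compounds + 1)]


def dense_block(spec: SyntheticSpec) -> tuple[tuple[str, ...], frozenset[str]]:
    """The planted dense bipartite block: (compound ids, target symbols).

    Every listed compound asserts every listed target, emulating a
    scaffold family with a shared target panel; the targets are drawn
    from the planted (consensus) pool so the block survives into the
    C-T network.  Sizes are clamped to the available compounds/planted
    symbols; either size 0 disables the block.
    """
    n_c = min(spec.dense_block_compounds, spec.n_compounds)
    n_t = min(spec.dense_block_targets, spec.planted_overlap)
    if n_c == 0 or n_t == 0:
        return (), frozenset()
    rng = np.random.default_rng([spec.rng_seed, 2])
    comps = tuple(sorted(rng.choice(compound_ids(spec), size=n_c, replace=False)))
    targets = frozenset(rng.choice(sorted(planted_symbols(spec)), size=n_t, replace=False))
    return comps, targets


def gen_compound_target_map(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate a compound->target assertion table.

    Each compound draws a Poisson-sized target set (>= 1) from the
    compound pool plus the planted shared pool (planted symbols
    oversampled by ``planted_weight``); every planted symbol is
    guaranteed at least one asserting compound.  Compounds in the
    planted dense block additionally assert the whole block target
    panel, and their random draws are unbiased so the panel dominates
    their consensus-target degree.  Rows carry a source database tag,
    and a small fraction are deliberately duplicated under a second tag.

    Returns a DataFrame with columns ``compound_id``, ``target_symbol``,
    ``source_tag``.
    """
    planted, _, compound_pool = _pools(spec)
    rng = np.random.default_rng([spec.rng_seed, 1])
    drawable = np.array(sorted(planted) + sorted(compound_pool))
    weights = np.concatenate([
        np.full(len(planted), spec.planted_weight),
        np.ones(len(compound_pool)),
    ])
    probs = weights / weights.sum()
    uniform = np.full(len(drawable), 1.0 / len(drawable))
    compounds = compound_ids(spec)
    block_compounds, block_targets = dense_block(spec)

    assigned: dict[str, set[str]] = {}
    for cid in compounds:
        size = max(1, int(rng.poisson(spec.targets_per_compound)))
        size = min(size, len(drawable))
        p = uniform if cid in block_compounds else probs
        picks = rng.choice(drawable, size=size, replace=False, p=p)
        assigned[cid] = set(picks)
        if cid in block_compounds:
            assigned[cid] |= block_targets

    covered = set().union(*assigned.values())
    for sym in sorted(planted - covered):
        assigned[compounds[int(rng.integers(len(compounds)))]].add(sym)

    rows = []
    for cid in compounds:
        for sym in sorted(assigned[cid]):
            tag = SOURCE_TAGS[int(rng.integers(len(SOURCE_TAGS)))]
            rows.append((cid, sym, tag))
            if rng.random() < DUPLICATE_ASSERTION_RATE:
                other = [t for t in SOURCE_TAGS if t != tag]
                rows.append((cid, sym, other[int(rng.integers(len(other)))]))
    return pd.DataFrame(rows, columns=["compound_id", "target_symbol", "source_tag"])


def gen_disease_targets(spec: SyntheticSpec) -> frozenset[str]:
    """Generate the disease target list: planted symbols plus disease-only fill.

    Its intersection with the compound-target union from the same spec is
    exactly the planted set.
    """
    planted, disease_only, _ = _pools(spec)
    out = planted | disease_only
    assert len(out) == spec.n_disease_targets
    return out


def gen_ppi_edges(genes, density: float, score_range=(0.4, 1.0), seed: int = 0) -> pd.DataFrame:
    """Erdos-Renyi scored edges over a gene set.

    Undirected, no self-loops, no duplicate unordered pairs; each pair is
    kept with probability ``density`` and scored uniformly on
    ``score_range``.  Returns a (node1, node2, score) DataFrame.
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a PPI table")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0,1]")
    lo, hi = score_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("score_range must be ordered and within [0,1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i, u in enumerate(genes):
        for v in genes[i + 1:]:
            if rng.random() < density:
                rows.append((u, v, lo + (hi - lo) * rng.random()))
    return pd.DataFrame(rows, columns=["node1", "node2", "score"])


# ---------------------------------------------------------------------------
# pharmacokinetic profiles


@dataclass(frozen=True)
class PKTruth:
    """Ground-truth one-compartment oral-absorption model.

    C(t) = dose*ka / (V_F*(ka-ke)) * (exp(-ke*t) - exp(-ka*t)), t in
    minutes.  Defaults give Tmax ~= 51 min and terminal half-life
    ~= 139 min, within the range the emulated study reports.

    dose in mg/kg; V_F is apparent volume over bioavailability in
    ml/kg so that concentrations come out in ng/ml.
    """

    dose: float = 10.0           # mg/kg
    ka: float = 0.05             # 1/min
    ke: float = 0.005            # 1/min
    V_F: float = 20_000.0        # ml/kg
    noise_cv: float = 0.25
    sample_times: tuple = DEFAULT_SAMPLE_TIMES

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0:
            raise ValueError("ka and ke must be positive")
        if math.isclose(self.ka, self.ke):
            raise ValueError("ka must differ from ke (flip-flop degenerate model)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        t = np.asarray(self.sample_times, dtype=float)
        if t.size < 2 or (np.diff(t) <= 0).any() or t[0] < 0:
            raise ValueError("sample_times must be >= 2 strictly increasing times, first >= 0")

    def concentration(self, t) -> np.ndarray:
        """Noiseless concentration (ng/ml) at time(s) t in minutes."""
        t = np.asarray(t, dtype=float)
        dose_ng = self.dose * 1e6  # mg -> ng
        amp = dose_ng * self.ka / (self.V_F * (self.ka - self.ke))
        return amp * (np.exp(-self.ke * t) - np.exp(-self.ka * t))

    @property
    def tmax_min(self) -> float:
        """Closed-form time of the concentration peak, minutes."""
        return math.log(self.ka / self.ke) / (self.ka - self.ke)

    @property
    def t_half_h(self) -> float:
        """Terminal half-life, hours."""
        return math.log(2) / self.ke / 60.0

    @property
    def auc_inf(self) -> float:
        """Analytic AUC from 0 to infinity, ng/ml * h."""
        dose_ng = self.dose * 1e6
        amp = dose_ng * self.ka / (self.V_F * (self.ka - self.ke))
        return amp * (1.0 / self.ke - 1.0 / self.ka) / 60.0


def gen_concentration_profiles(truth: PKTruth, n_subjects: int, seed: int = 0) -> pd.DataFrame:
    """Simulate per-subject concentration-time profiles.

    Noise is multiplicative lognormal with coefficient of variation
    ``truth.noise_cv`` (mean-one, so the expected curve is the model
    curve); concentrations can never go negative.

    Returns a DataFrame with columns ``subject``, ``time_min``, ``conc``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.asarray(truth.sample_times, dtype=float)
    clean = truth.concentration(times)
    sigma2 = math.log(1.0 + truth.noise_cv**2)
    sigma = math.sqrt(sigma2)
    rows = []
    for subj in range(1, n_subjects + 1):
        if truth.noise_cv > 0:
            factors = np.exp(rng.normal(-sigma2 / 2.0, sigma, size=times.size))
        else:
            factors = np.ones_like(times)
        conc = clean * factors
        for t, c in zip(times, conc):
            rows.append((f"S{subj:02d}", t, c))
    return pd.DataFrame(rows, columns=["subject", "time_min", "conc"])


def gen_gmt_terms(genes, n_terms: int, term_size: int, seed: int = 0,
                  planted_query: frozenset | None = None,
                  planted_fraction: float = 0.8) -> list[tuple[str, str, frozenset[str]]]:
    """Random annotation terms over a gene universe, optionally with one
    planted enriched term.

    When ``planted_query`` is given, the first term ("T000_planted") draws
    ``planted_fraction`` of its members from the query set, so it should
    rank first in an over-representation test of that query.
    """
    genes = sorted(set(genes))
    rng = np.random.default_rng(seed)
    terms = []
    if planted_query is not None:
        query = sorted(planted_query)
        n_from_query = max(1, int(round(planted_fraction * term_size)))
        n_from_query = min(n_from_query, len(query))
        members = set(rng.choice(query, size=n_from_query, replace=False))
        rest = [g for g in genes if g not in members]
        fill = term_size - len(members)
        if fill > 0:
            members |= set(rng.choice(rest, size=min(fill, len(rest)), replace=False))
        terms.append(("T000_planted", "planted enriched term", frozenset(members)))
    for i in range(1, n_terms + 1):
        size = min(term_size, len(genes))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        terms.append((f"T{i:03d}", f"random term {i}", members))
    return terms
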