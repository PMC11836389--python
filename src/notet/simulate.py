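"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be emulated here: 4PL-shaped
dose-response tables with Gaussian noise, an oxRRBS-style methylome (paired
BS/oxBS binomial counts on a synthetic chromosome with matching CpG-island
and functional-element BED tracks, plus planted hyper/hypo effects in the
treated condition), and promoter-beta-anticorrelated expression values.

All generators are pure functions of their spec (which includes the seed):
the same spec yields byte-identical outputs.

The synthetic chromosome layout is built so that annotation round-trips:
island sites sit inside island intervals, shore sites within 2 kb of an
island edge, shelf sites 2-4 kb away, and open-sea sites in a separate
region more than 4 kb from any island.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .methylome import SHELF_BP, SHORE_BP
from .quant import four_pl

__all__ = [
    "DoseResponseSimSpec",
    "MethylomeSimSpec",
    "SynthMethylome",
    "synth_dose_response",
    "synth_oxrrbs",
    "synth_expression",
]


@dataclass(frozen=True)
class DoseResponseSimSpec:
    """Ground truth and sampling plan for a synthetic dose-response table.

    Defaults mimic the NO-donor inhibition assay: full response at low dose
    falling to zero at high dose (negative Hill slope), IC50 at 165 uM, eight
    doses spanning the assayed 15-1200 uM range, noise sd 5% of Top, and
    three replicates per dose (the assay's biological replication).
    """

    bottom: float = 0.0
    top: float = 100.0
    log_ic50: float = float(np.log10(165.0))
    hill: float = -1.0
    doses: tuple = tuple(np.geomspace(15.0, 1200.0, 8).round(3))
    noise_sd: float = 5.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise InvalidParameterError("doses must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")


def synth_dose_response(spec: DoseResponseSimSpec) -> tuple[pd.DataFrame, dict]:
    """4PL responses plus Gaussian noise; returns (table, truth record)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(1, spec.n_replicates + 1):
        doses = np.asarray(spec.doses, dtype=float)
        y = four_pl(np.log10(doses), spec.bottom, spec.top, spec.log_ic50, spec.hill)
        y = y + rng.normal(0.0, spec.noise_sd, size=len(doses))
        for d, r in zip(doses, y):
            rows.append((d, r, rep))
    table = pd.DataFrame(rows, columns=["dose", "response", "replicate"])
    truth = {
        "bottom": spec.bottom,
        "top": spec.top,
        "log_ic50": spec.log_ic50,
        "ic50": 10.0 ** spec.log_ic50,
        "hill": spec.hill,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return table, truth


def _default_class_proportions() -> dict:
    # Open-sea dominant, structurally like an RRBS CpG complement.
    return {"island": 0.10, "shore": 0.15, "shelf": 0.15, "open_sea": 0.60}


def _default_beta_5mc() -> dict:
    # Islands mostly unmethylated, open sea mostly methylated.
    return {"island": 0.10, "shore": 0.25, "shelf": 0.40, "open_sea": 0.55}


def _default_beta_5hmc() -> dict:
    return {"island": 0.03, "shore": 0.05, "shelf": 0.05, "open_sea": 0.05}


def _default_feature_proportions() -> dict:
    return {
        "promoter": 0.10,
        "5'UTR": 0.03,
        "3'UTR": 0.03,
        "exon": 0.15,
        "intron": 0.35,
        "enhancer": 0.05,
        "super_enhancer": 0.02,
        "intergenic": 0.27,
    }


@dataclass(frozen=True)
class MethylomeSimSpec:
    """Plan for a synthetic oxRRBS methylome with planted NO effects.

    ``effect_fraction_hyper`` / ``effect_fraction_hypo`` are fractions of all
    sites receiving a planted +/- ``effect_size`` change of ``effect_mark``
    beta in the treated condition; ``effect_classes`` optionally restricts
    the planted sites to given CpG classes (e.g. ``("open_sea",)``).
    Coverage is Poisson around ``coverage_mean`` per assay and replicate.
    """

    n_sites: int = 1000
    class_proportions: dict = field(default_factory=_default_class_proportions)
    beta_5mc: dict = field(default_factory=_default_beta_5mc)
    beta_5hmc: dict = field(default_factory=_default_beta_5hmc)
    beta_jitter: float = 0.05
    feature_proportions: dict = field(default_factory=_default_feature_proportions)
    coverage_mean: float = 50.0
    effect_fraction_hyper: float = 0.0
    effect_fraction_hypo: float = 0.0
    effect_size: float = 0.3
    effect_mark: str = "5mC"
    effect_classes: tuple | None = None
    replicates: int = 2
    chrom: str = "chrS1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise InvalidParameterError("n_sites must be >= 1")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise InvalidParameterError("class_proportions must sum to 1")
        for name, table in (("beta_5mc", self.beta_5mc), ("beta_5hmc", self.beta_5hmc)):
            for cls, b in table.items():
                if not 0.0 <= b <= 1.0:
                    raise InvalidParameterError(f"{name}[{cls!r}] outside [0, 1]")
        for cls in self.class_proportions:
            if self.beta_5mc.get(cls, 0) + self.beta_5hmc.get(cls, 0) > 1.0:
                raise InvalidParameterError(
                    f"beta_5mc + beta_5hmc > 1 for class {cls!r}"
                )
        if not self.coverage_mean > 0:
            raise InvalidParameterError("coverage_mean must be positive")
        if self.effect_mark not in ("5mC", "5hmC"):
            raise InvalidParameterError("effect_mark must be 5mC or 5hmC")
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")


@dataclass
class SynthMethylome:
    """Generated count table, matching BED tracks, and the ground truth."""

    counts: pd.DataFrame
    islands: pd.DataFrame
    features: pd.DataFrame
    truth: pd.DataFrame
    spec: MethylomeSimSpec


# Synthetic chromosome geometry (bp).
_BLOCK = 20_000          # one island block per spacing unit
_ISLAND_START = 8_000    # island interval within its block
_ISLAND_LEN = 1_000
_SITES_PER_ISLAND = 5


def synth_oxrrbs(spec: MethylomeSimSpec) -> SynthMethylome:
    """Generate a paired BS/oxBS count table with known per-site truth.

    Sites are laid out on one synthetic chromosome so that the emitted
    island BED reproduces each site's intended CpG class under the standard
    distance rules.  Counts are Binomial(total, beta) with Poisson totals;
    the treated condition shifts the planted sites' target beta by the
    planted effect (clipped to keep beta_5mC + beta_5hmC inside [0, 1]).
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_proportions)
    n_per = {c: int(round(spec.class_proportions[c] * spec.n_sites)) for c in classes}
    # fix rounding drift on the largest class
    drift = spec.n_sites - sum(n_per.values())
    n_per[max(n_per, key=n_per.get)] += drift

    n_islands = max(1, -(-n_per.get("island", 0) // _SITES_PER_ISLAND),
                    -(-max(n_per.get("shore", 0), n_per.get("shelf", 0)) // 2))
    island_rows = []
    for i in range(n_islands):
        s = i * _BLOCK + _ISLAND_START
        island_rows.append((spec.chrom, s, s + _ISLAND_LEN, "island"))
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end", "label"])

    def _spread(n: int) -> list[int]:
        """Split n sites as evenly as possible across the island blocks."""
        return [n // n_islands + (1 if i < n % n_islands else 0)
                for i in range(n_islands)]

    positions: list[int] = []
    site_class: list[str] = []
    for cls in classes:
        n = n_per[cls]
        if n == 0:
            continue
        if cls == "open_sea":
            # own territory, > 4 kb beyond every island block
            base = n_islands * _BLOCK + 100_000
            positions.extend(base + j * 100 + int(rng.integers(0, 50))
                             for j in range(n))
        else:
            # unique offsets per block keep classes in disjoint distance bands
            lo, hi = {"island": (0, _ISLAND_LEN),
                      "shore": (1, SHORE_BP),
                      "shelf": (SHORE_BP + 1, SHELF_BP)}[cls]
            for blk, cnt in enumerate(_spread(n)):
                if cnt == 0:
                    continue
                anchor = blk * _BLOCK + _ISLAND_START
                if cls != "island":
                    anchor += _ISLAND_LEN - 1  # distance measured from island edge
                offs = rng.choice(np.arange(lo, hi), size=cnt, replace=False)
                positions.extend(anchor + int(o) for o in sorted(offs))
        site_class.extend([cls] * n)

    order = np.argsort(positions, kind="stable")
    positions = [int(positions[i]) for i in order]
    site_class = [site_class[i] for i in order]

    feat_labels = list(spec.feature_proportions)
    feat_p = np.array([spec.feature_proportions[f] for f in feat_labels], dtype=float)
    feat_p = feat_p / feat_p.sum()
    site_feature = rng.choice(feat_labels, size=len(positions), p=feat_p)

    feature_rows = [
        (spec.chrom, pos, pos + 2, feat)
        for pos, feat in zip(positions, site_feature)
        if feat != "intergenic"
    ]
    features = pd.DataFrame(feature_rows, columns=["chrom", "start", "end", "label"])

    b5mc = np.array([spec.beta_5mc[c] for c in site_class])
    b5hmc = np.array([spec.beta_5hmc[c] for c in site_class])
    if spec.beta_jitter > 0:
        b5mc = np.clip(b5mc + rng.uniform(-spec.beta_jitter, spec.beta_jitter,
                                          len(b5mc)), 0.0, 1.0)
    b5mc = np.minimum(b5mc, 1.0 - b5hmc)

    # plant effects among sites with room for the full shift
    n_sites = len(positions)
    effect_dir = np.zeros(n_sites, dtype=int)
    base = b5mc if spec.effect_mark == "5mC" else b5hmc
    other = b5hmc if spec.effect_mark == "5mC" else b5mc
    eligible_mask = np.ones(n_sites, dtype=bool)
    if spec.effect_classes is not None:
        eligible_mask = np.isin(site_class, list(spec.effect_classes))
    room_up = (base + spec.effect_size + other) <= 0.98
    room_down = (base - spec.effect_size) >= 0.02
    for frac, direction, room in (
        (spec.effect_fraction_hyper, 1, room_up),
        (spec.effect_fraction_hypo, -1, room_down),
    ):
        n_want = int(round(frac * n_sites))
        pool = np.flatnonzero(eligible_mask & room & (effect_dir == 0))
        if n_want > len(pool):
            raise InvalidParameterError(
                f"cannot plant {n_want} effects; only {len(pool)} eligible sites"
            )
        chosen = rng.choice(pool, size=n_want, replace=False)
        effect_dir[chosen] = direction

    shift = effect_dir * spec.effect_size
    if spec.effect_mark == "5mC":
        b5mc_t = np.clip(b5mc + shift, 0.0, 1.0 - b5hmc)
        b5hmc_t = b5hmc
    else:
        b5hmc_t = np.clip(b5hmc + shift, 0.0, 1.0 - b5mc)
        b5mc_t = b5mc

    count_rows = []
    for cond, m5, h5 in (("control", b5mc, b5hmc), ("treated", b5mc_t, b5hmc_t)):
        p_bs = np.clip(m5 + h5, 0.0, 1.0)
        p_ox = m5
        for rep in range(1, spec.replicates + 1):
            bs_tot = rng.poisson(spec.coverage_mean, n_sites)
            ox_tot = rng.poisson(spec.coverage_mean, n_sites)
            bs_meth = rng.binomial(bs_tot, p_bs)
            ox_meth = rng.binomial(ox_tot, p_ox)
            for i, pos in enumerate(positions):
                count_rows.append((spec.chrom, pos, ".", cond, rep, "BS",
                                   int(bs_meth[i]), int(bs_tot[i])))
                count_rows.append((spec.chrom, pos, ".", cond, rep, "oxBS",
                                   int(ox_meth[i]), int(ox_tot[i])))
    counts = pd.DataFrame(
        count_rows,
        columns=["chrom", "pos", "strand", "condition", "replicate",
                 "assay", "meth", "total"],
    )

    truth = pd.DataFrame({
        "chrom": spec.chrom,
        "pos": positions,
        "cpg_class": site_class,
        "feature": site_feature,
        "beta_5mc_control": b5mc,
        "beta_5hmc_control": b5hmc,
        "beta_5mc_treated": b5mc_t,
        "beta_5hmc_treated": b5hmc_t,
        "effect_mark": spec.effect_mark,
        "effect_direction": effect_dir,
    })
    return SynthMethylome(counts=counts, islands=islands, features=features,
                          truth=truth, spec=spec)


def synth_expression(
    promoter_betas,
    slope: float = -3.0,
    intercept: float = 5.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Log-expression coupled (negatively) to promoter beta values.

    ``log_expr = intercept + slope * beta + N(0, noise_sd)`` per gene; the
    default negative slope emulates promoter methylation repressing
    transcription.
    """
    if slope > 0:
        raise InvalidParameterError("coupling slope must be <= 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    betas = pd.Series(promoter_betas, dtype=float)
    rng = np.random.default_rng(seed)
    expr = intercept + slope * betas + rng.normal(0.0, noise_sd, size=len(betas))
    expr.name = "log_expression"
    return expr
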