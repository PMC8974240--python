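"""Synthetic structured inbred-panel genotypes and replicated phenotypes.

Genotypes follow a Balding–Nichols-style model: each SNP has an ancestral
allele frequency, each subpopulation draws its own frequency from a Beta
distribution whose spread is controlled by ``fst``, and inbred accessions are
coded as homozygous dosages in {0, 2}.  Admixed accessions sample from a
50/50 mixture of two parent subpopulation frequencies.

Phenotypes are generated from a planted truth set: per-trait QTL effects on
dosages, directed trait-to-trait path coefficients (a DAG), an accession
polygenic term, environment and replicate offsets, and per-record noise.
Bounded traits are clamped, and traits tagged ``exp`` are exponentiated so
their raw distributions are right-skewed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelConfig",
    "PlantedQtl",
    "TruthSet",
    "GenotypeMatrix",
    "simulate_genotypes",
    "simulate_traits",
    "write_truth",
    "read_truth",
    "default_config",
    "default_truth",
]

_BASES = np.array(["A", "C", "G", "T"])

PHENO_COLUMNS = ["accession", "environment", "replicate", "trait", "value"]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class PanelConfig:
    """Parameters of the synthetic diversity panel.

    Attributes
    ----------
    subpop_sizes
        Number of accessions per (pure) subpopulation, keyed by label.
    n_admixed
        Accessions built as 50/50 mixtures of two random subpopulations.
    chrom_lengths
        Length in bp of each chromosome; chromosome names are 1..k.
    n_snps
        Total SNP count, distributed across chromosomes proportionally to
        their lengths.
    fst
        Balding–Nichols divergence parameter in [0, 1); 0 means no drift.
    ancestral_maf_range
        (lo, hi) bounds of the uniform ancestral allele-frequency draw.
    missing_rate
        Fraction of dosages masked as missing (default 0: deterministic
        fixtures).
    ld_rho
        Local linkage disequilibrium as a Markov copy probability: each
        accession copies its previous dosage on the chromosome with
        probability ``ld_rho`` instead of drawing fresh.  Default 0 (no LD),
        which preserves per-SNP allele-frequency expectations.
    inbred
        When True (default) dosages are homozygous {0, 2}.
    """

    subpop_sizes: Mapping[str, int]
    n_admixed: int = 0
    n_chromosomes: int = 12
    chrom_lengths: Sequence[int] | None = None
    n_snps: int = 5000
    fst: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    ld_rho: float = 0.0
    inbred: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_lengths is None:
            self.chrom_lengths = [30_000_000] * self.n_chromosomes
        self.chrom_lengths = list(self.chrom_lengths)
        self.n_chromosomes = len(self.chrom_lengths)
        if any(length <= 0 for length in self.chrom_lengths):
            raise ConfigError("chromosome lengths must be > 0")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigError(f"fst must lie in [0, 1), got {self.fst}")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if any(size <= 0 for size in self.subpop_sizes.values()):
            raise ConfigError("subpopulation sizes must be positive")
        if self.n_admixed < 0:
            raise ConfigError("n_admixed must be >= 0")
        if self.n_admixed > 0 and len(self.subpop_sizes) < 2:
            raise ConfigError("admixture requires at least two subpopulations")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigError("ld_rho must lie in [0, 1)")

    @property
    def n_accessions(self) -> int:
        return sum(self.subpop_sizes.values()) + self.n_admixed


@dataclass
class PlantedQtl:
    """A causal SNP with a per-copy effect on one trait.

    ``linked`` carries pleiotropy: additional (trait, per-copy effect) pairs
    attached to the same SNP.
    """

    trait: str
    chromosome: str
    position: int
    effect: float
    linked: tuple[tuple[str, float], ...] = ()

    def effects(self) -> list[tuple[str, float]]:
        return [(self.trait, self.effect), *[(t, e) for t, e in self.linked]]


@dataclass
class TruthSet:
    """Planted genetic and structural truth for trait simulation."""

    planted_qtl: list[PlantedQtl] = field(default_factory=list)
    dag_arcs: list[tuple[str, str, float]] = field(default_factory=list)
    intercepts: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    polygenic_sd: dict[str, float] = field(default_factory=dict)
    env_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    rep_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    transform: dict[str, str] = field(default_factory=dict)  # identity | exp
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    environments: list[str] = field(default_factory=lambda: ["env1", "env2"])
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if _dag_has_cycle(self.traits(), [(u, v) for u, v, _ in self.dag_arcs]):
            raise ConfigError("dag_arcs contain a cycle")

    def traits(self) -> list[str]:
        """All trait names, in a stable order (intercept keys first)."""
        seen: dict[str, None] = {}
        for t in self.intercepts:
            seen.setdefault(t)
        for q in self.planted_qtl:
            for t, _ in q.effects():
                seen.setdefault(t)
        for u, v, _ in self.dag_arcs:
            seen.setdefault(u)
            seen.setdefault(v)
        return list(seen)


@dataclass
class GenotypeMatrix:
    """Accession-by-SNP dosage matrix with map positions.

    ``dosages`` holds counts of the alternate allele as floats (NaN =
    missing); inbred panels only carry {0, 2}.  ``snp_map`` is a DataFrame
    with columns ``snp, chrom, pos, ref, alt`` (1-based positions, strictly
    increasing within each chromosome).
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    accessions: list[str]
    subpops: list[str]
    inbred: bool = True

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accessions), len(self.snp_map)):
            raise ValueError("dosage shape does not match accessions x snp_map")
        if self.inbred:
            bad = np.isin(self.dosages[~np.isnan(self.dosages)], (0.0, 2.0), invert=True)
            if bad.any():
                raise ValueError("inbred panel contains non-homozygous dosages")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def snp_index(self, snp: str) -> int:
        idx = self.snp_map.index[self.snp_map["snp"] == snp]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP: {snp!r}")
        return int(idx[0])

    def locus_index(self, chrom: str, pos: int) -> int:
        mask = (self.snp_map["chrom"].astype(str) == str(chrom)) & (self.snp_map["pos"] == pos)
        idx = self.snp_map.index[mask]
        if len(idx) == 0:
            raise KeyError(f"no SNP at {chrom}:{pos}")
        return int(idx[0])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(),
            self.snp_map.copy().reset_index(drop=True),
            list(self.accessions),
            list(self.subpops),
            self.inbred,
        )


def _dag_has_cycle(nodes: Sequence[str], arcs: Sequence[tuple[str, str]]) -> bool:
    children: dict[str, list[str]] = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for u, v in arcs:
        children.setdefault(u, []).append(v)
        indeg[v] = indeg.get(v, 0) + 1
        indeg.setdefault(u, 0)
    queue = [n for n, d in indeg.items() if d == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for c in children.get(n, []):
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return seen < len(indeg)


def _topo_order(nodes: Sequence[str], arcs: Sequence[tuple[str, str]]) -> list[str]:
    order: list[str] = []
    remaining = list(nodes)
    parents = {n: {u for u, v in arcs if v == n} for n in nodes}
    while remaining:
        ready = [n for n in remaining if parents[n] <= set(order)]
        if not ready:
            raise ConfigError("dag_arcs contain a cycle")
        order.extend(ready)
        remaining = [n for n in remaining if n not in ready]
    return order


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Distinct sorted 1-based positions without materialising the range."""
    if n > length:
        raise ConfigError(f"cannot place {n} SNPs on a {length} bp chromosome")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=n))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:n])


def simulate_genotypes(config: PanelConfig) -> GenotypeMatrix:
    """Draw structured homozygous genotypes for the configured panel.

    Subpopulation allele frequencies follow
    ``Beta(p(1-fst)/fst, (1-p)(1-fst)/fst)`` around the ancestral frequency
    ``p``; ``fst = 0`` is the no-drift limit where every subpopulation uses
    ``p`` directly.  Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    subpops = list(config.subpop_sizes)

    # map: SNPs spread over chromosomes proportionally to length
    lengths = np.asarray(config.chrom_lengths, dtype=float)
    counts = np.floor(m * lengths / lengths.sum()).astype(int)
    for i in range(m - counts.sum()):  # distribute the remainder
        counts[i % len(counts)] += 1
    chroms: list[str] = []
    positions: list[int] = []
    for ci, (length, n_c) in enumerate(zip(config.chrom_lengths, counts), start=1):
        pos = _sample_positions(rng, int(length), int(n_c))
        chroms.extend([str(ci)] * int(n_c))
        positions.extend(int(p) for p in pos)

    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    snp_map = pd.DataFrame(
        {
            "snp": [f"S{c}_{p}" for c, p in zip(chroms, positions)],
            "chrom": chroms,
            "pos": positions,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )

    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    freqs = {}
    for sp in subpops:
        if config.fst == 0.0:
            freqs[sp] = p_anc.copy()
        else:
            a = p_anc * (1.0 - config.fst) / config.fst
            b = (1.0 - p_anc) * (1.0 - config.fst) / config.fst
            freqs[sp] = rng.beta(a, b)

    rows = []
    labels: list[str] = []
    accessions: list[str] = []
    k = 0
    for sp in subpops:
        for _ in range(config.subpop_sizes[sp]):
            rows.append(freqs[sp])
            labels.append(sp)
            accessions.append(f"acc{k:04d}")
            k += 1
    for _ in range(config.n_admixed):
        pa, pb = rng.choice(len(subpops), size=2, replace=False)
        rows.append(0.5 * (freqs[subpops[pa]] + freqs[subpops[pb]]))
        labels.append(f"ADM:{subpops[pa]}/{subpops[pb]}")
        accessions.append(f"acc{k:04d}")
        k += 1

    freq_matrix = np.vstack(rows)
    if config.inbred:
        dosages = 2.0 * (rng.random(freq_matrix.shape) < freq_matrix)
    else:
        dosages = (
            (rng.random(freq_matrix.shape) < freq_matrix).astype(float)
            + (rng.random(freq_matrix.shape) < freq_matrix)
        )
    if config.ld_rho > 0.0:
        # Markov copy along each chromosome: adjacent-SNP dosage correlation
        # ~ ld_rho per step, so significant hits come in local strings
        copy = rng.random(dosages.shape) < config.ld_rho
        chrom_arr = np.asarray(chroms)
        for j in range(1, dosages.shape[1]):
            if chrom_arr[j] != chrom_arr[j - 1]:
                continue
            cj = copy[:, j]
            dosages[cj, j] = dosages[cj, j - 1]
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    return GenotypeMatrix(dosages, snp_map, accessions, labels, inbred=config.inbred)


def simulate_traits(
    genotypes: GenotypeMatrix, truth: TruthSet, seed: int = 0
) -> pd.DataFrame:
    """Generate replicated long-format phenotypes from a planted truth set.

    Each accession's latent trait value is
    ``intercept + sum(effect * dosage) + polygenic + sum(coeff * centered
    parent latent)``; records add environment/replicate offsets and Gaussian
    noise, then apply the trait's transform (``exp`` for right-skewed raw
    scales) and bounds clamp.

    Returns a DataFrame with columns
    ``accession, environment, replicate, trait, value``.
    """
    rng = np.random.default_rng(seed)
    traits = truth.traits()
    order = _topo_order(traits, [(u, v) for u, v, _ in truth.dag_arcs])
    n = genotypes.n_accessions

    qtl_effects: dict[str, list[tuple[int, float]]] = {t: [] for t in traits}
    for q in truth.planted_qtl:
        try:
            j = genotypes.locus_index(q.chromosome, q.position)
        except KeyError as exc:
            raise KeyError(
                f"planted QTL for {q.trait} at {q.chromosome}:{q.position} "
                f"is not on the SNP map"
            ) from exc
        for trait, eff in q.effects():
            qtl_effects.setdefault(trait, []).append((j, eff))

    dos = genotypes.dosages
    col_means = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
    dos_filled = np.where(np.isnan(dos), col_means[None, :], dos)

    latent: dict[str, np.ndarray] = {}
    for t in order:
        u = np.full(n, truth.intercepts.get(t, 0.0))
        for j, eff in qtl_effects.get(t, []):
            u = u + eff * dos_filled[:, j]
        sd_g = truth.polygenic_sd.get(t, 0.0)
        if sd_g > 0:
            u = u + rng.normal(0.0, sd_g, size=n)
        for parent, child, coeff in truth.dag_arcs:
            if child == t:
                u = u + coeff * (latent[parent] - latent[parent].mean())
        latent[t] = u

    records = []
    for t in order:
        sd_e = truth.noise_sd.get(t, 0.0)
        env_off = truth.env_effects.get(t, {})
        rep_off = truth.rep_effects.get(t, {})
        for env in truth.environments:
            for rep in range(1, truth.n_replicates + 1):
                vals = latent[t] + env_off.get(env, 0.0) + rep_off.get(str(rep), 0.0)
                if sd_e > 0:
                    vals = vals + rng.normal(0.0, sd_e, size=n)
                if truth.transform.get(t, "identity") == "exp":
                    vals = np.exp(vals)
                if t in truth.bounds:
                    lo, hi = truth.bounds[t]
                    vals = np.clip(vals, lo, hi)
                for i, acc in enumerate(genotypes.accessions):
                    records.append((acc, env, rep, t, float(vals[i])))

    return pd.DataFrame(records, columns=PHENO_COLUMNS)


# ---------------------------------------------------------------------------
# truth-set round trip (JSON)

def write_truth(truth: TruthSet, path) -> None:
    payload = asdict(truth)
    payload["planted_qtl"] = [asdict(q) for q in truth.planted_qtl]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> TruthSet:
    with open(path) as fh:
        payload = json.load(fh)
    payload["planted_qtl"] = [
        PlantedQtl(
            trait=q["trait"],
            chromosome=q["chromosome"],
            position=int(q["position"]),
            effect=float(q["effect"]),
            linked=tuple((t, float(e)) for t, e in q.get("linked", [])),
        )
        for q in payload["planted_qtl"]
    ]
    payload["dag_arcs"] = [(u, v, float(c)) for u, v, c in payload["dag_arcs"]]
    payload["bounds"] = {t: (float(a), float(b)) for t, (a, b) in payload.get("bounds", {}).items()}
    return TruthSet(**payload)


# ---------------------------------------------------------------------------
# ready-made small panel emulating the study design

DEFAULT_SUBPOPS = {"AUS": 30, "IND": 54, "TEJ": 29, "TRJ": 28, "ARO": 6}

#: staged 9-trait causal graph used by the demo truth set:
#: development upstream, element concentrations intermediate, disease terminal
DEFAULT_ARCS = [
    ("DHD", "PHT", 0.6),
    ("DHD", "As", 0.02),
    ("PHT", "As", 0.002),
    ("PHT", "Cu", -0.004),
    ("PHT", "StHD", 0.04),
    ("As", "P", 0.5),
    ("As", "StHD", 1.5),
    ("Si", "Ca", 0.15),
    ("S", "Cu", 0.2),
]


def default_config(n_snps: int = 5000, seed: int = 0, **overrides) -> PanelConfig:
    """Panel configuration mimicking the study's composition at reduced scale."""
    kwargs = dict(
        subpop_sizes=dict(DEFAULT_SUBPOPS),
        n_admixed=20,
        chrom_lengths=[10_000_000] * 12,
        n_snps=n_snps,
        fst=0.15,
        ld_rho=0.85,
        seed=seed,
    )
    kwargs.update(overrides)
    return PanelConfig(**kwargs)


def default_truth(genotypes: GenotypeMatrix, seed: int = 0, n_qtl_per_trait: int = 2) -> TruthSet:
    """Plant pleiotropic QTL on the supplied map and wire the demo trait DAG.

    Effect sizes are the implementer's choice (heritabilities of the real
    panel are not published); defaults give common-ish causal alleles with
    sizable effects so desk-scale scans can recover them.
    """
    rng = np.random.default_rng(seed)
    traits = ["DHD", "PHT", "Si", "As", "P", "S", "Ca", "Cu", "StHD"]
    element = {"Si", "As", "P", "S", "Ca", "Cu"}

    intercepts = {
        "DHD": 95.0, "PHT": 110.0, "Si": 5.2, "As": -1.6, "P": 7.6,
        "S": 6.9, "Ca": 5.0, "Cu": 1.0, "StHD": 5.0,
    }
    noise_sd = {t: (0.25 if t in element else 1.0) for t in traits}
    noise_sd["StHD"] = 0.8
    polygenic_sd = {t: (0.3 if t in element else 3.0) for t in traits}
    polygenic_sd["StHD"] = 0.9
    env_effects = {t: {"env1": 0.0, "env2": (0.1 if t in element else 1.5)} for t in traits}

    effect_scale = {t: (0.35 if t in element else 3.0) for t in traits}
    effect_scale["StHD"] = 1.0

    planted: list[PlantedQtl] = []
    candidates = genotypes.snp_map.reset_index(drop=True)
    # prefer intermediate-frequency SNPs so planted QTL are detectable
    freqs = np.nanmean(genotypes.dosages, axis=0) / 2.0
    ok = np.where((freqs > 0.15) & (freqs < 0.85))[0]
    picks = rng.choice(ok, size=min(len(ok), n_qtl_per_trait * len(traits)), replace=False)
    it = iter(picks)
    for t in traits:
        for k in range(n_qtl_per_trait):
            try:
                j = int(next(it))
            except StopIteration:
                break
            row = candidates.iloc[j]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            linked: tuple[tuple[str, float], ...] = ()
            if t == "As" and k == 0:  # one pleiotropic locus: As & StHD
                linked = (("StHD", 0.5 * effect_scale["StHD"]),)
            planted.append(
                PlantedQtl(t, str(row["chrom"]), int(row["pos"]), sign * effect_scale[t], linked)
            )

    return TruthSet(
        planted_qtl=planted,
        dag_arcs=list(DEFAULT_ARCS),
        intercepts=intercepts,
        noise_sd=noise_sd,
        polygenic_sd=polygenic_sd,
        env_effects=env_effects,
        transform={t: "exp" for t in element},
        bounds={"StHD": (0.0, 9.0)},
    )
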