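"""Synthetic multiregional tumors with known clonal ground truth.

The generative model is deliberately minimal but statistically matched to
what multiregional exome data of a solid tumor look like:

* a *clone tree*: a founding (root) clone carrying the truncal mutations,
  plus user-declared subclones, each occupying a per-region cell fraction
  (a clone's fraction includes its descendants, so a parent's fraction is
  always >= the sum of its children's);
* a *neutral tail* per clone: passenger mutations whose within-clone
  frequency f is drawn from the density proportional to 1/f^2 truncated
  to [f_min, f_max], so the cumulative count M(f) grows linearly in 1/f
  with slope mu_eff (the effective mutation rate mu/beta);
* *read sampling*: per region, expected observed allele frequency

      AF = f_cell * m * rho / (rho * CN_t + (1 - rho) * 2)

  with tumor purity rho, local tumor copy number CN_t (2 unless the
  variant's gene lies in a declared copy-number event, in which case the
  mutation multiplicity m equals the event's major copy number), sequencing
  depth Poisson(depth_mean) and alt reads Binomial(depth, AF).

Everything downstream (filters, sharing spectra, CCF clonality, the 1/f
neutrality test, parsimony trees) is exercised against the emitted truth
table, which records each variant's clone, per-region cell fraction,
multiplicity, and whether it is truly clonal (truncal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from multiregion import variants as vmod
from multiregion.errors import ConfigurationError

ROOT_CLONE = 0


@dataclass
class SimConfig:
    """Configuration of one synthetic multiregional tumor.

    tree_splits entries are ``(parent_clone_id, child_fraction)`` or
    ``(parent_clone_id, child_fraction, regions)`` where ``regions`` is a
    sequence of 0-based region indices the subclone is confined to (all
    regions when omitted).  Fractions are of the whole tumor-cell
    population in that region and include the subclone's descendants.
    """

    n_regions: int = 5
    n_clonal: int = 30
    tree_splits: Sequence[tuple] = field(default_factory=list)
    n_private: int = 30
    mu_eff: float = 10.0
    f_min: float = 0.05
    f_max: float = 0.4
    depth_mean: float = 200.0
    purity: float | Sequence[float] = 0.8
    cn_events: Sequence[tuple] = field(default_factory=list)
    p_synonymous: float = 0.35
    n_lymph_node: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.n_clonal < 0 or self.n_private < 0:
            raise ConfigurationError("mutation counts must be >= 0")
        if not (0 < self.f_min < self.f_max <= 1):
            raise ConfigurationError(
                f"require 0 < f_min < f_max <= 1, got ({self.f_min}, {self.f_max})"
            )
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        for rho in self.purities():
            if not 0 < rho <= 1:
                raise ConfigurationError(f"purity {rho} outside (0, 1]")
        if self.mu_eff < 0:
            raise ConfigurationError("mu_eff must be >= 0")
        if not 0 <= self.p_synonymous <= 1:
            raise ConfigurationError("p_synonymous outside [0, 1]")
        if self.n_lymph_node > self.n_regions:
            raise ConfigurationError("n_lymph_node exceeds n_regions")

    def purities(self) -> np.ndarray:
        rho = np.asarray(self.purity, dtype=float)
        if rho.ndim == 0:
            rho = np.full(self.n_regions, float(rho))
        if rho.shape != (self.n_regions,):
            raise ConfigurationError("purity must be scalar or length n_regions")
        return rho

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = json.load(fh)
        data["tree_splits"] = [tuple(s) for s in data.get("tree_splits", [])]
        data["cn_events"] = [tuple(e) for e in data.get("cn_events", [])]
        return cls(**data)


@dataclass
class Clone:
    id: int
    parent: int | None
    fractions: np.ndarray  # per-region cell fraction, descendants included
    mutations: list[str] = field(default_factory=list)


@dataclass
class SubcloneTree:
    """Clone phylogeny with per-region cell fractions and private mutations."""

    clones: dict[int, Clone]
    n_regions: int

    @property
    def root(self) -> Clone:
        return self.clones[ROOT_CLONE]

    def children(self, clone_id: int) -> list[Clone]:
        return [c for c in self.clones.values() if c.parent == clone_id]

    def ancestry(self, clone_id: int) -> list[int]:
        """Clone ids from root to ``clone_id`` inclusive."""
        path = [clone_id]
        while self.clones[path[-1]].parent is not None:
            path.append(self.clones[path[-1]].parent)
        return path[::-1]

    def mutation_set(self, clone_id: int) -> list[str]:
        """All mutations carried by cells of this clone (ancestors included)."""
        out: list[str] = []
        for cid in self.ancestry(clone_id):
            out.extend(self.clones[cid].mutations)
        return out

    def validate(self) -> None:
        for clone in self.clones.values():
            kids = self.children(clone.id)
            if kids:
                residual = clone.fractions - sum(k.fractions for k in kids)
                if (residual < -1e-9).any():
                    raise ConfigurationError(
                        f"children of clone {clone.id} exceed its cell fraction"
                    )
        if not np.allclose(self.root.fractions, 1.0):
            raise ConfigurationError("root clone fraction must be 1 in every region")


@dataclass(frozen=True)
class VariantTruth:
    clone_id: int
    truly_clonal: bool
    multiplicity: int
    cell_fractions: tuple  # per region
    gene: str
    effect: str


@dataclass
class SimTruth:
    """Ground truth per simulated variant."""

    records: dict[str, VariantTruth]
    region_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for vid, t in self.records.items():
            row = {
                "variant_id": vid,
                "clone_id": t.clone_id,
                "truly_clonal": t.truly_clonal,
                "multiplicity": t.multiplicity,
                "gene": t.gene,
                "effect": t.effect,
            }
            for rid, f in zip(self.region_ids, t.cell_fractions):
                row[f"cell_fraction_{rid}"] = f
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

def simulate_tree(config: SimConfig) -> SubcloneTree:
    """Build the clone tree declared by ``config`` (deterministic).

    Mutations attached here are the *fixed* ones: truncal mutations on the
    root and ``n_private`` private mutations per subclone.  The neutral
    tail is drawn later (it is random) in :func:`make_truth`.
    """
    config.validate()
    nR = config.n_regions
    clones = {ROOT_CLONE: Clone(ROOT_CLONE, None, np.ones(nR))}
    clones[ROOT_CLONE].mutations = [f"v{ROOT_CLONE}_{i}" for i in range(config.n_clonal)]

    for k, split in enumerate(config.tree_splits, start=1):
        if len(split) == 2:
            parent, frac = split
            regions = range(nR)
        else:
            parent, frac, regions = split
        if parent not in clones:
            raise ConfigurationError(f"split {k} references unknown parent clone {parent}")
        if not 0 < frac < 1:
            raise ConfigurationError(
                f"split {k} under clone {parent}: fraction {frac} outside (0, 1)"
            )
        fractions = np.zeros(nR)
        for r in regions:
            if not 0 <= r < nR:
                raise ConfigurationError(f"split {k}: region index {r} out of range")
            fractions[r] = frac
        child = Clone(k, parent, fractions)
        child.mutations = [f"v{k}_{i}" for i in range(config.n_private)]
        clones[k] = child
        # validate headroom under this parent as we build
        taken = sum(c.fractions for c in clones.values() if c.parent == parent)
        if (taken > clones[parent].fractions + 1e-9).any():
            raise ConfigurationError(
                f"children of clone {parent} exceed its cell fraction after split {k}"
            )

    tree = SubcloneTree(clones, nR)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Neutral tail
# ---------------------------------------------------------------------------

def neutral_inverse_cdf(u, f_min: float, f_max: float):
    """Quantile function of the 1/f^2 density truncated to [f_min, f_max].

    Parameterized on the survival scale: u=0 maps to f_max, u=1 to f_min.
    """
    u = np.asarray(u, dtype=float)
    return 1.0 / (1.0 / f_max + u * (1.0 / f_min - 1.0 / f_max))


def expected_tail_count(mu_eff: float, f_min: float, f_max: float) -> float:
    """Expected number of tail mutations above f_min: mu_eff*(1/f_min - 1/f_max)."""
    return mu_eff * (1.0 / f_min - 1.0 / f_max)


def sample_neutral_vafs(
    mu_eff: float,
    f_min: float,
    f_max: float,
    rng: np.random.Generator,
    n: int | None = None,
) -> np.ndarray:
    """Draw neutral-tail frequencies from the truncated 1/f^2 density.

    The number of draws is Poisson with mean mu_eff*(1/f_min - 1/f_max)
    unless ``n`` fixes it explicitly.
    """
    if f_min >= f_max:
        raise ConfigurationError(f"f_min {f_min} must be < f_max {f_max}")
    if n is None:
        n = rng.poisson(expected_tail_count(mu_eff, f_min, f_max))
    return neutral_inverse_cdf(rng.uniform(size=int(n)), f_min, f_max)


# ---------------------------------------------------------------------------
# Truth assembly and read sampling
# ---------------------------------------------------------------------------

_EFFECT_CHOICES = ("missense", "nonsense", "frameshift")
_EFFECT_WEIGHTS = (0.8, 0.1, 0.1)


def _draw_effect(rng: np.random.Generator, p_syn: float) -> str:
    if rng.uniform() < p_syn:
        return "synonymous"
    return rng.choice(_EFFECT_CHOICES, p=_EFFECT_WEIGHTS)


def make_truth(tree: SubcloneTree, config: SimConfig, rng: np.random.Generator) -> SimTruth:
    """Attach genes/effects/multiplicities and the neutral tail; emit truth.

    Tail mutations are region-independent frequency draws *within* their
    host clone: their cell fraction in region r is clone_fraction[r] * f.
    A variant is truly clonal iff it belongs to the root's founding
    (truncal) mutation set, i.e. sits in every tumor cell of every region.
    """
    region_ids = [f"R{r + 1}" for r in range(config.n_regions)]
    event_by_gene = {e[0]: e for e in config.cn_events}
    records: dict[str, VariantTruth] = {}
    gene_counter = 0

    def assign_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"G{gene_counter:05d}"

    # genes taking part in CN events are assigned to the first few truncal
    # variants so that declared events actually cover simulated mutations
    event_genes = list(event_by_gene)

    for clone in tree.clones.values():
        for j, vid in enumerate(clone.mutations):
            gene = (
                event_genes.pop(0)
                if clone.id == ROOT_CLONE and event_genes
                else assign_gene()
            )
            mult = 1
            if gene in event_by_gene:
                mult = max(1, int(event_by_gene[gene][3]))
            records[vid] = VariantTruth(
                clone_id=clone.id,
                truly_clonal=(clone.id == ROOT_CLONE),
                multiplicity=mult,
                cell_fractions=tuple(clone.fractions),
                gene=gene,
                effect=_draw_effect(rng, config.p_synonymous),
            )

    for clone in tree.clones.values():
        tail = sample_neutral_vafs(config.mu_eff, config.f_min, config.f_max, rng)
        for i, f in enumerate(tail):
            vid = f"t{clone.id}_{i}"
            records[vid] = VariantTruth(
                clone_id=clone.id,
                truly_clonal=False,
                multiplicity=1,
                cell_fractions=tuple(clone.fractions * f),
                gene=assign_gene(),
                effect=_draw_effect(rng, config.p_synonymous),
            )

    return SimTruth(records, region_ids)


def expected_af(f_cell: float, m: int, rho: float, cn_t: float, cn_n: float = 2.0) -> float:
    """Expected observed allele frequency of a variant at cell fraction
    f_cell with multiplicity m, purity rho, tumor/normal copy number."""
    return f_cell * m * rho / (rho * cn_t + (1.0 - rho) * cn_n)


def sample_reads(
    tree: SubcloneTree,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> vmod.VariantTable:
    """Draw sequencing reads for every variant x region; emit a VariantTable.

    Depth ~ Poisson(depth_mean); alt reads ~ Binomial(depth, expected AF).
    A matched normal column ("N", depth drawn, zero alt reads) is always
    included.  Variant annotations default to clean somatic calls
    (no flags, population AF 0, known somatic).
    """
    config.validate()
    rho = config.purities()
    event_by_gene = {e[0]: e for e in config.cn_events}
    region_ids = truth.region_ids

    vrows, crows = [], []
    pos = 0
    for vid, t in truth.records.items():
        pos += 100
        vrows.append(
            {
                "variant_id": vid,
                "chrom": "1",
                "pos": pos,
                "ref": "A",
                "alt": "T",
                "gene": t.gene,
                "effect": t.effect,
                "homopolymer": False,
                "strand_bias": False,
                "blacklist": False,
                "population_af": 0.0,
                "known_somatic": True,
                "census_gene": False,
            }
        )
        event = event_by_gene.get(t.gene)
        for r, rid in enumerate(region_ids):
            cn_t = 2.0
            m = 1
            if event is not None and r in event[1]:
                cn_t = float(event[2])
                m = t.multiplicity
            af = expected_af(t.cell_fractions[r], m, rho[r], cn_t)
            depth = int(rng.poisson(config.depth_mean))
            alt = int(rng.binomial(depth, min(af, 1.0))) if depth > 0 else 0
            crows.append(
                {"variant_id": vid, "sample_id": rid, "depth": depth, "alt_reads": alt}
            )
        depth_n = int(rng.poisson(config.depth_mean))
        crows.append(
            {"variant_id": vid, "sample_id": "N", "depth": depth_n, "alt_reads": 0}
        )

    tissues = ["primary"] * config.n_regions
    for r in range(config.n_regions - config.n_lymph_node, config.n_regions):
        tissues[r] = "lymph_node"
    samples = pd.DataFrame(
        {"purity": list(rho) + [1.0], "tissue": tissues + ["normal"]},
        index=pd.Index(region_ids + ["N"], name="sample_id"),
    )
    variants = pd.DataFrame(vrows).set_index("variant_id")
    calls = pd.DataFrame(crows)
    return vmod.make_table(f"SIM{config.seed}", samples, variants, calls)


def simulate_tumor(config: SimConfig) -> tuple[SubcloneTree, SimTruth, vmod.VariantTable]:
    """Full simulation: clone tree -> truth table -> read counts.

    Each stage consumes its own child stream of the configured seed, so
    outputs are byte-identical across runs with the same config.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    truth_ss, reads_ss = ss.spawn(2)
    tree = simulate_tree(config)
    truth = make_truth(tree, config, np.random.default_rng(truth_ss))
    table = sample_reads(tree, truth, config, np.random.default_rng(reads_ss))
    return tree, truth, table


# ---------------------------------------------------------------------------
# Balance-factor fixture
# ---------------------------------------------------------------------------

def simulate_balanced_presence(
    n_regions: int,
    n_truncal: int,
    n_subclonal: int,
    g: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Presence matrix whose apparent-clonal curve is exactly geometric.

    Truncal variants are present everywhere; each subclonal variant is
    present in each region independently with probability ``g`` (the
    balance factor), so the expected count of variants shared by n random
    regions is n_truncal + n_subclonal * g**n.  Used as the ground-truth
    fixture for balance-factor recovery.
    """
    if not 0 < g < 1:
        raise ConfigurationError(f"balance factor g {g} outside (0, 1)")
    cols = [f"R{r + 1}" for r in range(n_regions)]
    truncal = np.ones((n_truncal, n_regions), dtype=bool)
    sub = rng.uniform(size=(n_subclonal, n_regions)) < g
    sub = sub[sub.any(axis=1)]  # a variant absent everywhere is never observed
    data = np.vstack([truncal, sub])
    index = [f"c{i}" for i in range(n_truncal)] + [f"s{i}" for i in range(len(sub))]
    return pd.DataFrame(data, index=index, columns=cols)
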