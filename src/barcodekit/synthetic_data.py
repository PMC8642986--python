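"""Synthetic multi-marker community barcode datasets with ground truth.

The generator emulates a community barcoding campaign: tens of species
sampled at several sites with 3-6 individuals per species per site, four
markers of very different variability and recovery rate (an rbcL-like
conserved plastid region, a fast high-GC nuclear ITS2-like region, and two
moderately variable plastid regions, one of them indel-rich), plus F1
hybrids and infraspecific haplotype structure.

Generative model
----------------
1. A pure-birth (Yule) species tree, scaled to a chosen root-to-tip height
   in expected substitutions per site.
2. Per marker, a root sequence drawn with the marker's GC bias and evolved
   along the tree under the Kimura two-parameter substitution process with
   a per-marker rate multiplier — matching the K2P distance used by the
   analysis makes distance recovery analytically checkable.
3. Within each species, populations diverge by a fixed stem branch and
   individuals within a population coalesce under a Kingman genealogy with
   per-site mutation parameter theta (scaled by the marker rate), so that
   the Watterson and pi estimators are unbiased for the marker's effective
   theta and between-population distances stochastically exceed
   within-population distances.
4. Indel-rich markers receive full-column gap events shared by random
   species subsets; the emitted data are aligned by construction.
5. Each individual's each marker is dropped independently with one minus
   the marker's recovery probability (failed PCR/sequencing).
6. F1 hybrids carry IUPAC two-base codes at every parental diagnostic site
   of the nuclear marker and the designated mother's plastid sequences.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .seq_io import PAIR_TO_CODE, BarcodeDataset, MarkerAlignment, SpecimenRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class MarkerModel:
    """Evolutionary and technical profile of one marker."""

    name: str
    length: int
    rate: float = 1.0  # substitution-rate multiplier on the species tree
    kappa: float = 2.0  # transition/transversion rate ratio
    gc: float = 0.5  # root-sequence GC fraction
    indel_rate: float = 0.0  # expected number of shared gap events
    recovery: float = 1.0  # P(marker recovered for an individual)
    genome: str = "chloroplast"  # "chloroplast" (maternal) or "nuclear"


def default_markers() -> List[MarkerModel]:
    """Four markers mirroring the study's sequencing panel: a conserved,
    near-universally recovered plastid marker; a fast, GC-rich nuclear
    marker; and two harder-to-recover plastid markers, one indel-rich."""
    return [
        MarkerModel("rbcL", 570, rate=0.25, gc=0.441, indel_rate=0.0, recovery=0.986),
        MarkerModel("ITS2", 679, rate=1.0, gc=0.597, indel_rate=0.0, recovery=0.879, genome="nuclear"),
        MarkerModel("matK", 902, rate=0.6, gc=0.339, indel_rate=3.0, recovery=0.700),
        MarkerModel("trnH-psbA", 1411, rate=0.8, gc=0.276, indel_rate=25.0, recovery=0.728),
    ]


@dataclass
class SimConfig:
    """Community simulation parameters.

    Defaults follow the emulated sampling design: ~tens of species split
    into true-mangrove/associate/coastal groups, 2 populations per species
    drawn from a shared site pool, 3-6 individuals per population, and the
    four-marker panel of :func:`default_markers`.
    """

    seed: int = 0
    n_species: int = 30
    birth_rate: float = 1.0
    tree_height: float = 0.15  # root-to-tip, expected subs/site at rate 1
    markers: List[MarkerModel] = field(default_factory=default_markers)
    n_populations: int = 2
    min_individuals: int = 3
    max_individuals: int = 6
    n_sites: int = 10
    theta: float = 0.002  # per-site within-population diversity at rate 1
    between_pop_divergence: float = 0.002  # expected extra pair divergence
    n_hybrids: int = 2
    # Parent selection: "diagnosable" draws F1 parents only among species
    # that differ from every other species by >= min_parent_divergence
    # sites on the hybrid-typing (nuclear, else first) marker — emulating
    # hybrids between well-differentiated, unambiguously identifiable
    # species; "random" draws any distinct pair.
    hybrid_parent_rule: str = "diagnosable"
    min_parent_divergence: int = 8
    group_fractions: Tuple[float, float, float] = (0.4, 0.2, 0.4)

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_hybrids and self.n_species < 2:
            raise ValueError("hybrids require at least 2 species")
        if not self.markers:
            raise ValueError("at least one marker required")
        for m in self.markers:
            if not (0.0 <= m.recovery <= 1.0):
                raise ValueError(f"marker {m.name}: recovery must be in [0,1]")
            if m.rate <= 0 or m.kappa <= 0 or m.length <= 0:
                raise ValueError(f"marker {m.name}: rates and length must be positive")
        if self.theta < 0 or self.between_pop_divergence < 0:
            raise ValueError("diversity parameters must be non-negative")
        if not (2 <= self.min_individuals or self.min_individuals >= 1):
            raise ValueError("min_individuals must be >= 1")
        if self.max_individuals < self.min_individuals:
            raise ValueError("max_individuals < min_individuals")
        if self.hybrid_parent_rule not in ("diagnosable", "random"):
            raise ValueError(f"unknown hybrid_parent_rule {self.hybrid_parent_rule!r}")


@dataclass
class TruthManifest:
    """Simulator ground truth, for use as a test oracle."""

    species_tree: str  # Newick over species labels
    species: List[str]
    groups: Dict[str, str]
    populations: Dict[str, List[str]]  # species -> site ids
    hybrids: List[Dict[str, str]]  # id, parent1, parent2, mother, species_label
    theta_effective: Dict[str, float]  # marker -> theta * rate
    config: Dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


class _Node:
    __slots__ = ("children", "length", "name", "t0", "codes")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.children: List["_Node"] = []
        self.length = length
        self.name = name
        self.t0 = 0.0
        self.codes: Optional[np.ndarray] = None

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def _yule_tree(n: int, birth_rate: float, rng: np.random.Generator) -> Tuple[_Node, List[_Node]]:
    """Ultrametric pure-birth tree with n extant tips (unit: time)."""
    root = _Node()
    if n == 1:
        root.length = rng.exponential(1.0 / birth_rate)
        return root, [root]
    active = [root]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(int(rng.integers(k)))
        node.length = t - node.t0
        for _ in range(2):
            child = _Node()
            child.t0 = t
            node.children.append(child)
            active.append(node.children[-1])
    T = t + rng.exponential(1.0 / (birth_rate * n))
    for leaf in active:
        leaf.length = T - leaf.t0
    return root, active


def _scale_tree(root: _Node, height: float) -> None:
    """Scale so the crown root-to-tip depth equals ``height``; the pre-split
    root stem is dropped first (it would otherwise dominate the depth)."""
    root.length = 0.0

    def depth(node: _Node) -> float:
        return node.length + (max(depth(c) for c in node.children) if node.children else 0.0)

    current = depth(root)
    if current <= 0:
        return
    f = height / current

    def apply(node: _Node) -> None:
        node.length *= f
        for c in node.children:
            apply(c)

    apply(root)


def _k2p_step_probs(t: float, kappa: float) -> Tuple[float, float, float]:
    """(P_same, P_transition, P_each_transversion) after branch length t
    (expected substitutions/site) under the normalized K2P chain."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_tv = 0.25 * (1.0 - e1)
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    return 1.0 - p_ti - 2.0 * p_tv, p_ti, p_tv


def evolve_codes(codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a 0..3-coded sequence for branch length t under K2P."""
    if t <= 0:
        return codes.copy()
    p_same, p_ti, p_tv = _k2p_step_probs(t, kappa)
    u = rng.random(codes.shape)
    out = codes.copy()
    ti = (u >= p_same) & (u < p_same + p_ti)
    tv1 = (u >= p_same + p_ti) & (u < p_same + p_ti + p_tv)
    tv2 = u >= p_same + p_ti + p_tv  # remaining mass = the other transversion
    out[ti] ^= 2  # A<->G, C<->T
    out[tv1] = (codes[tv1] + 1) % 4
    out[tv2] = (codes[tv2] + 3) % 4
    return out


def _evolve_along(node: _Node, codes: np.ndarray, rate: float, kappa: float, rng) -> None:
    node.codes = evolve_codes(codes, node.length * rate, kappa, rng)
    for c in node.children:
        _evolve_along(c, node.codes, rate, kappa, rng)


def _coalescent_tips(
    ancestor: np.ndarray, k: int, theta: float, kappa: float, rng: np.random.Generator
) -> List[np.ndarray]:
    """Sequences of k individuals under a Kingman coalescent genealogy.

    Coalescent time is measured so that a random pair has expected TMRCA 1;
    the per-site mutation rate per unit time is theta/2, so the expected
    pairwise difference equals theta and E[S] = theta * a_{n-1} * L.
    """
    if k == 1:
        return [evolve_codes(ancestor, 0.0, kappa, rng)]
    nodes = [_Node(name=str(i)) for i in range(k)]
    active = list(nodes)
    t = 0.0
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i1, i2 = sorted(rng.choice(j, size=2, replace=False))
        b = active.pop(i2)
        a = active.pop(i1)
        parent = _Node()
        parent.t0 = t
        for child in (a, b):
            child.length = t - child.t0
            parent.children.append(child)
        active.append(parent)
    root = active[0]
    mu = theta / 2.0

    def run(node: _Node, codes: np.ndarray) -> None:
        node.codes = evolve_codes(codes, node.length * mu, kappa, rng)
        for c in node.children:
            run(c, node.codes)

    run(root, ancestor)
    out: List[Optional[np.ndarray]] = [None] * k
    for leaf in nodes:
        out[int(leaf.name)] = leaf.codes
    return out  # type: ignore[return-value]


def _root_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def _codes_to_str(codes: np.ndarray, gap_mask: Optional[np.ndarray] = None) -> str:
    chars = _BASES[codes].copy()
    if gap_mask is not None:
        chars[gap_mask] = ord("-")
    return chars.tobytes().decode("ascii")


def _eligible_parent_pairs(
    species: List[str],
    codes: Dict[str, np.ndarray],
    rule: str,
    min_div: int,
) -> List[Tuple[str, str]]:
    """Candidate F1 parent pairs under the configured selection rule.

    Under "diagnosable", both parents must differ from *every* other
    species by at least ``min_div`` sites on the typing marker, so the
    parent pair is recoverable in principle from the hybrid's heterozygous
    sites; "random" admits any distinct pair.
    """
    pairs = []
    n = len(species)
    div = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            div[i, j] = div[j, i] = int(
                (codes[species[i]] != codes[species[j]]).sum()
            )
    for i in range(n):
        for j in range(i + 1, n):
            if rule == "random":
                pairs.append((species[i], species[j]))
                continue
            ok_i = all(div[i, k] >= min_div for k in range(n) if k != i)
            ok_j = all(div[j, k] >= min_div for k in range(n) if k != j)
            if ok_i and ok_j:
                pairs.append((species[i], species[j]))
    return pairs


def simulate_community(cfg: SimConfig) -> Tuple[BarcodeDataset, TruthManifest]:
    """Generate a dataset plus its ground-truth manifest. Deterministic in cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    species = [f"Species{i + 1:03d}" for i in range(cfg.n_species)]
    root, tips = _yule_tree(cfg.n_species, cfg.birth_rate, rng)
    _scale_tree(root, cfg.tree_height)
    for tip, name in zip(tips, species):
        tip.name = name

    group_names = ("true_mangrove", "associate", "coastal")
    bounds = np.cumsum(cfg.group_fractions) / sum(cfg.group_fractions)
    groups = {}
    for i, sp in enumerate(species):
        frac = (i + 0.5) / cfg.n_species
        groups[sp] = group_names[int(np.searchsorted(bounds, frac))]

    sites = [f"S{i + 1:02d}" for i in range(cfg.n_sites)]
    pop_of: Dict[str, List[str]] = {}
    n_pops = min(cfg.n_populations, cfg.n_sites)
    for sp in species:
        pop_of[sp] = sorted(rng.choice(cfg.n_sites, size=n_pops, replace=False).tolist())
    pop_sites = {sp: [sites[i] for i in idx] for sp, idx in pop_of.items()}

    specimens: List[SpecimenRecord] = []
    alignments: Dict[str, Dict[str, str]] = {m.name: {} for m in cfg.markers}

    # Individual layout is drawn once, shared by all markers.
    layout: List[Tuple[str, str, str]] = []  # (specimen_id, species, site)
    for si, sp in enumerate(species):
        for site in pop_sites[sp]:
            k = int(rng.integers(cfg.min_individuals, cfg.max_individuals + 1))
            for ind in range(k):
                layout.append((f"{sp}_{site}_{ind + 1:02d}", sp, site))
    for sid, sp, site in layout:
        specimens.append(
            SpecimenRecord(specimen_id=sid, species=sp, group=groups[sp], site_id=site)
        )

    species_codes: Dict[str, Dict[str, np.ndarray]] = {}  # marker -> species -> codes
    gap_masks: Dict[str, Dict[str, np.ndarray]] = {}  # marker -> species -> bool mask
    for marker in cfg.markers:
        root_seq = _root_sequence(marker.length, marker.gc, rng)
        _evolve_along(root, root_seq, marker.rate, marker.kappa, rng)
        species_codes[marker.name] = {tip.name: tip.codes for tip in tips}

        masks = {sp: np.zeros(marker.length, dtype=bool) for sp in species}
        n_events = rng.poisson(marker.indel_rate)
        for _ in range(n_events):
            width = int(rng.geometric(0.15))
            start = int(rng.integers(0, max(1, marker.length - width)))
            affected = rng.random(cfg.n_species) < 0.5
            if not affected.any() or affected.all():
                continue
            for sp, hit in zip(species, affected):
                if hit:
                    masks[sp][start : start + width] = True
        gap_masks[marker.name] = masks

        theta_m = cfg.theta * marker.rate
        stem = cfg.between_pop_divergence * marker.rate / 2.0
        per_species_inds: Dict[Tuple[str, str], List[str]] = {}
        for sid, sp, site in layout:
            per_species_inds.setdefault((sp, site), []).append(sid)
        for (sp, site), inds in per_species_inds.items():
            pop_anc = evolve_codes(species_codes[marker.name][sp], stem, marker.kappa, rng)
            tips_codes = _coalescent_tips(pop_anc, len(inds), theta_m, marker.kappa, rng)
            for sid, codes in zip(inds, tips_codes):
                if rng.random() < marker.recovery:
                    alignments[marker.name][sid] = _codes_to_str(codes, masks[sp])

    # Hybrids: F1s between species pairs drawn under the parent selection
    # rule, typed on the nuclear marker when one exists.  The first parent
    # is the designated mother.
    hybrid_registry: List[Dict[str, str]] = []
    if cfg.n_hybrids:
        typing = next(
            (m for m in cfg.markers if m.genome == "nuclear"), cfg.markers[0]
        )
        eligible = _eligible_parent_pairs(
            species, species_codes[typing.name], cfg.hybrid_parent_rule,
            cfg.min_parent_divergence,
        )
        if not eligible:
            raise ValueError(
                "config infeasible: no diagnosable hybrid parent pair "
                f"(min_parent_divergence={cfg.min_parent_divergence})"
            )
        for h in range(cfg.n_hybrids):
            p1, p2 = eligible[int(rng.integers(len(eligible)))]
            if rng.random() < 0.5:
                p1, p2 = p2, p1
            label = f"{p1}_x_{p2}"
            hid = f"HYB{h + 1:02d}_{label}"
            specimens.append(
                SpecimenRecord(
                    specimen_id=hid, species=label, group="hybrid",
                    site_id=pop_sites[p1][0],
                )
            )
            hybrid_registry.append(
                {"id": hid, "parent1": p1, "parent2": p2, "mother": p1, "species_label": label}
            )

    for marker in cfg.markers:
        masks = gap_masks[marker.name]
        for reg in hybrid_registry:
            c1 = species_codes[marker.name][reg["parent1"]]
            c2 = species_codes[marker.name][reg["parent2"]]
            mother_mask = masks[reg["mother"]]
            if marker.genome == "nuclear":
                chars = bytearray(_codes_to_str(
                    species_codes[marker.name][reg["mother"]], None).encode())
                het = c1 != c2
                for col in np.nonzero(het)[0]:
                    pair = frozenset((chr(_BASES[c1[col]]), chr(_BASES[c2[col]])))
                    chars[col] = ord(PAIR_TO_CODE[pair])
                seq = chars.decode()
                seq = "".join(
                    "-" if mother_mask[i] else ch for i, ch in enumerate(seq)
                )
            else:
                seq = _codes_to_str(species_codes[marker.name][reg["mother"]], mother_mask)
            if rng.random() < marker.recovery:
                alignments[marker.name][reg["id"]] = seq

    dataset = BarcodeDataset(
        specimens=specimens,
        alignments={
            name: MarkerAlignment(name, seqs) for name, seqs in alignments.items() if seqs
        },
    )
    manifest = TruthManifest(
        species_tree=root.newick() + ";",
        species=species,
        groups=groups,
        populations=pop_sites,
        hybrids=hybrid_registry,
        theta_effective={m.name: cfg.theta * m.rate for m in cfg.markers},
        config=dataclasses.asdict(cfg),
    )
    return dataset, manifest


# Hand-built deterministic fixtures live alongside the stochastic generator.
from .fixtures import Fixture, fixture_suite  # noqa: E402,F401
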