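"""Simulation of species-structured barcode alignments with known truth.

Datasets are generated under an explicit two-level divergence model: a root
sequence is drawn uniformly over {A,C,G,T}; species ancestors evolve from it
along a star (default) or Yule species tree scaled so that allospecific
ancestor pairs are separated by ``inter_divergence`` expected
substitutions/site; individuals then evolve from their species ancestor so
conspecific pairs are separated by ``intra_divergence``. Substitutions follow
the Kimura two-parameter process with transition/transversion rate ratio
``kappa``, i.e. exactly the model the K2P distance estimator inverts, so
realized distances converge on the configured divergences as sequence length
grows. Alignment gaps, when requested, are injected independently per site
per sequence after substitution.

Sampling depth per species is controlled by a fixed count, an explicit list,
or a singleton fraction, letting simulated datasets reproduce the
individual/species/singleton structure of real barcode compilations.
"""

from __future__ import annotations

import random as _random
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import LabeledAlignment, SequenceRecord
from .exceptions import ValidationError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def evolve_k2p(
    codes: np.ndarray, branch_length: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve an encoded sequence along a branch under the K2P process.

    ``branch_length`` is the expected number of substitutions per site;
    ``kappa`` is the transition/transversion *rate* ratio (alpha/beta).
    Site fates are independent; the returned array is a new copy.
    """
    if branch_length < 0:
        raise ValidationError("branch_length must be >= 0")
    if kappa <= 0:
        raise ValidationError("kappa must be > 0")
    if branch_length == 0:
        return codes.copy()
    # Split d = (alpha + 2 beta) t into alpha*t and beta*t via kappa.
    bt = branch_length / (kappa + 2.0)
    at = kappa * bt
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * bt) - 0.5 * np.exp(-2.0 * (at + bt))
    p_tv_each = 0.25 - 0.25 * np.exp(-4.0 * bt)
    p_same = 1.0 - p_ts - 2.0 * p_tv_each

    u = rng.random(codes.shape[0])
    out = codes.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv_each)
    tv2_mask = u >= p_same + p_ts + p_tv_each
    out[ts_mask] = codes[ts_mask] ^ 2  # A<->G, C<->T
    out[tv1_mask] = codes[tv1_mask] ^ 1
    out[tv2_mask] = codes[tv2_mask] ^ 3
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Divergences are expected substitutions/site (branch-length scale), not
    observed p-distances. Defaults describe a clearly structured barcode
    dataset: 20 species of 3 individuals, 500 bp, intraspecific divergence
    0.01 versus interspecific 0.15, and a mild transition bias (kappa = 2).
    """

    n_species: int = 20
    individuals_per_species: int | Sequence[int] = 3
    seq_length: int = 500
    inter_divergence: float = 0.15
    intra_divergence: float = 0.01
    kappa: float = 2.0
    gap_rate: float = 0.0
    singleton_fraction: float = 0.0
    species_tree: str = "star"
    region: str = "SIM"
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValidationError("n_species must be >= 2")
        if self.seq_length < 1:
            raise ValidationError("seq_length must be >= 1")
        if self.intra_divergence < 0 or self.inter_divergence < 0:
            raise ValidationError("divergences must be >= 0")
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")
        if not (0.0 <= self.gap_rate < 1.0):
            raise ValidationError("gap_rate must be in [0, 1)")
        if not (0.0 <= self.singleton_fraction <= 1.0):
            raise ValidationError("singleton_fraction must be in [0, 1]")
        if self.species_tree not in ("star", "yule"):
            raise ValidationError("species_tree must be 'star' or 'yule'")
        self.species_counts()  # validate feasibility eagerly

    def species_counts(self) -> list[int]:
        """Resolved per-species individual counts, in species order."""
        ips = self.individuals_per_species
        if isinstance(ips, int):
            if ips < 1:
                raise ValidationError("individuals_per_species must be >= 1")
            n_single = round(self.n_species * self.singleton_fraction)
            return [1] * n_single + [ips] * (self.n_species - n_single)
        counts = list(ips)
        if len(counts) != self.n_species:
            raise ValidationError(
                f"{len(counts)} per-species counts given for {self.n_species} species"
            )
        if any(c < 1 for c in counts):
            raise ValidationError("every species needs >= 1 individual")
        return counts

    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["individuals_per_species"], int):
            d["individuals_per_species"] = list(d["individuals_per_species"])
        return d


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset, for recovery tests.

    ``expected_divergence(a, b)`` is the expected substitutions/site between
    an individual of species ``a`` and one of ``b`` (ancestor path length
    plus both intraspecific tips; just the intraspecific divergence when
    ``a == b``).
    """

    species_of: dict[str, str]  # record label -> species
    ancestors: dict[str, str]  # species -> ancestral residues
    pair_divergence: dict[tuple[str, str], float]  # sorted species pair -> expected
    intra_divergence: float

    def expected_divergence(self, sp_a: str, sp_b: str) -> float:
        if sp_a == sp_b:
            return self.intra_divergence
        return self.pair_divergence[tuple(sorted((sp_a, sp_b)))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.species_of),
                "species": list(self.species_of.values()),
            }
        )


def _decode(codes: np.ndarray, gap_mask: np.ndarray | None = None) -> str:
    out = _BASES[codes]
    s = out.tobytes().decode("ascii")
    if gap_mask is not None and gap_mask.any():
        chars = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
        chars[gap_mask] = ord("-")
        s = chars.tobytes().decode("ascii")
    return s


def _yule_ancestor_paths(
    n_species: int, inter: float, rng: np.random.Generator
) -> tuple[list[np.ndarray], np.ndarray]:
    """Topology/branch plan for a Yule species tree scaled to mean depth.

    Returns per-species root-to-tip edge stacks handled by the caller.
    Implemented via dendropy's pure-birth simulator with edge lengths
    rescaled so the mean tip-pair path length equals ``inter``.
    """
    from dendropy.simulate import treesim

    pyr = _random.Random(int(rng.integers(0, 2**31 - 1)))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=pyr
    )
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    dists = [
        pdm.patristic_distance(taxa[i], taxa[j])
        for i in range(len(taxa))
        for j in range(i + 1, len(taxa))
    ]
    mean_d = float(np.mean(dists))
    scale = inter / mean_d if mean_d > 0 else 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree, taxa


def simulate_dataset(cfg: SimulationConfig) -> tuple[LabeledAlignment, TruthTable]:
    """Generate a labeled alignment plus its ground truth, reproducibly.

    Species are named ``Sim_sp001`` ... and samples ``i01`` ... within each
    species; the emitted alignment passes :mod:`barcodeval.core_io`
    validation unmodified, and identical configs (including seed) produce
    byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.species_counts()
    L = cfg.seq_length
    species_names = [f"Sim_sp{i + 1:03d}" for i in range(cfg.n_species)]

    root = rng.integers(0, 4, size=L).astype(np.uint8)

    pair_divergence: dict[tuple[str, str], float] = {}
    if cfg.species_tree == "star":
        half = cfg.inter_divergence / 2.0
        ancestors = [evolve_k2p(root, half, cfg.kappa, rng) for _ in species_names]
        for i in range(cfg.n_species):
            for j in range(i + 1, cfg.n_species):
                pair_divergence[(species_names[i], species_names[j])] = (
                    cfg.inter_divergence + cfg.intra_divergence
                )
    else:
        tree, taxa = _yule_ancestor_paths(cfg.n_species, cfg.inter_divergence, rng)
        # Evolve root->tip along the scaled Yule tree, one ancestor per tip.
        seqs: dict = {tree.seed_node: root}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            bl = node.edge.length or 0.0
            seqs[node] = evolve_k2p(seqs[node.parent_node], bl, cfg.kappa, rng)
        tip_of = {leaf.taxon: leaf for leaf in tree.leaf_node_iter()}
        ancestors = [seqs[tip_of[t]] for t in taxa]
        pdm = tree.phylogenetic_distance_matrix()
        for i in range(cfg.n_species):
            for j in range(i + 1, cfg.n_species):
                key = (species_names[i], species_names[j])
                pair_divergence[key] = (
                    float(pdm.patristic_distance(taxa[i], taxa[j]))
                    + cfg.intra_divergence
                )

    records: list[SequenceRecord] = []
    species_of: dict[str, str] = {}
    half_intra = cfg.intra_divergence / 2.0
    for sp, anc, count in zip(species_names, ancestors, counts):
        for k in range(count):
            ind = evolve_k2p(anc, half_intra, cfg.kappa, rng)
            gap_mask = rng.random(L) < cfg.gap_rate if cfg.gap_rate > 0 else None
            rec = SequenceRecord(
                sample_id=f"i{k + 1:02d}",
                species=sp,
                residues=_decode(ind, gap_mask),
                region=cfg.region,
            )
            records.append(rec)
            species_of[rec.label] = sp

    truth = TruthTable(
        species_of=species_of,
        ancestors={sp: _decode(anc) for sp, anc in zip(species_names, ancestors)},
        pair_divergence=pair_divergence,
        intra_divergence=cfg.intra_divergence,
    )
    return LabeledAlignment(records=records, region=cfg.region), truth


def emulate_table1_shape(
    row: Mapping[str, float],
    intra_divergence: float | None = None,
    **overrides,
) -> SimulationConfig:
    """Build a config reproducing a real dataset's structural counts.

    ``row`` must provide ``n_individuals``, ``n_species``, ``n_singletons``
    and ``alignment_length``; an optional ``overall_k2p_pct`` target chooses
    divergences so the pooled mean pairwise K2P lands near that value.
    Non-singleton species split the remaining individuals as evenly as
    possible (each receiving at least two).
    """
    n_ind = int(row["n_individuals"])
    n_sp = int(row["n_species"])
    n_single = int(row["n_singletons"])
    length = int(row["alignment_length"])

    if n_single > n_sp:
        raise ValidationError(f"{n_single} singletons exceed {n_sp} species")
    n_multi = n_sp - n_single
    remaining = n_ind - n_single
    if n_multi == 0:
        if remaining != 0:
            raise ValidationError("all species are singletons but individuals remain")
        counts: list[int] = [1] * n_single
    else:
        if remaining < 2 * n_multi:
            raise ValidationError(
                f"{remaining} individuals cannot give {n_multi} non-singleton "
                "species >= 2 each"
            )
        base, extra = divmod(remaining, n_multi)
        counts = [1] * n_single + [base + (1 if i < extra else 0) for i in range(n_multi)]

    target = row.get("overall_k2p_pct")
    if target is not None:
        m = float(target) / 100.0
        c = np.array(counts)
        intra_pairs = float(np.sum(c * (c - 1) // 2))
        total_pairs = n_ind * (n_ind - 1) / 2.0
        f_inter = (total_pairs - intra_pairs) / total_pairs
        intra = intra_divergence if intra_divergence is not None else min(0.01, m / 4.0)
        inter = max((m - intra) / f_inter, 0.0) if f_inter > 0 else 0.0
    else:
        intra = intra_divergence if intra_divergence is not None else 0.01
        inter = 0.15

    return SimulationConfig(
        n_species=n_sp,
        individuals_per_species=counts,
        seq_length=length,
        intra_divergence=intra,
        inter_divergence=inter,
        **overrides,
    )
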