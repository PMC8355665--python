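"""Synthetic collagen-like datasets with a full truth channel.

The generator emulates the statistical structure the analysis pipeline
assumes about fish collagen (I):

* three chain partitions of 1058/1041/1062 helical sites evolving on a
  shared time-calibrated tree at per-site rates near 0.00067/0.00088/0.00094
  substitutions per site per Ma (so realized rates rank α3 > α2 > α1);
* structural invariants frozen during simulation — glycine at every third
  helical position, conserved K/R tryptic boundaries, and the α1/α3
  diagnostic T32/33 window (helical 334–350, K vs Q at its ninth residue);
* α3 absent from a minority of taxa (dash-filled downstream);
* tetraploid taxa carrying A/B isoform pairs diverged by ~3–10%;
* within-taxon α1/α3 divergence far above the isoform band (the two chains
  descend from a gene duplication and are routinely mislabelled for one
  another; observed divergence is ~25–29%, this generator realizes ~30–40%).

Every substitution event is logged, so tests can replay the mutation
history from the root sequence and must reproduce each tip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import references as refs
from .dayhoff import MODEL_ORDER, SubstitutionModel, dayhoff_model
from .records import CHAIN_LENGTHS, CHAIN_ORDER, ChainRecord, ValidationError

_AA_INDEX = {aa: i for i, aa in enumerate(MODEL_ORDER)}


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic collagen dataset.

    Defaults are the study conditions the pipeline targets: canonical chain
    lengths, the per-chain substitution rates of the empirical rate table,
    a 430-Ma root (calibrated bony-fish scale), 15% of taxa lacking α3
    (85% carry the three-chain arrangement), ~10% tetraploid taxa with
    isoform pairs diverged 3–10%, and α1/α3 paralog roots diverged 5%
    (realized within-taxon α1/α3 divergence ~30–40% after descent).
    """

    n_taxa: int = 20
    tree_newick: str | None = None  # fixed tree overrides birth–death sampling
    birth_rate: float = 0.015  # per lineage per Ma
    death_rate: float = 0.005
    root_age: float = 430.0  # Ma
    chain_lengths: dict[str, int] = field(
        default_factory=lambda: dict(CHAIN_LENGTHS)
    )
    site_rates: dict[str, float] = field(
        default_factory=lambda: {
            "alpha1": 0.00067, "alpha2": 0.00088, "alpha3": 0.00094,
        }
    )
    alpha3_missing_fraction: float = 0.15
    tetraploid_fraction: float = 0.10
    isoform_divergence: tuple[float, float] = (0.03, 0.10)
    # divergence between the α1 and α3 paralogs at the species root; the two
    # chains then accumulate ~30% further independent divergence over the
    # default 430-Ma tree, so the realized within-taxon α1/α3 difference sits
    # just above the empirically observed 25–29% (uniform within-chain rates
    # saturate more slowly than real, rate-heterogeneous collagen sites)
    alpha3_root_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for chain, r in self.site_rates.items():
            if not r >= 0:
                raise ValidationError(f"site rate for {chain} must be non-negative")
        for name in ("alpha3_missing_fraction", "tetraploid_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        lo, hi = self.isoform_divergence
        if not 0 <= lo <= hi <= 1:
            raise ValidationError("isoform_divergence band must satisfy 0 <= lo <= hi <= 1")
        if self.tree_newick is None:
            if not (self.birth_rate > self.death_rate >= 0):
                raise ValidationError("need birth_rate > death_rate >= 0")
            if not self.root_age > 0:
                raise ValidationError("root_age must be positive")
        if self.n_taxa < 2:
            raise ValidationError("need at least 2 taxa")
        for chain, L in self.chain_lengths.items():
            if not L > 0:
                raise ValidationError(f"chain length for {chain} must be positive")


# ---------------------------------------------------------------------------
# time-tree sampling

def _depth_cdf(t: np.ndarray, birth: float, death: float) -> np.ndarray:
    """Unnormalised CDF of node depths in a reconstructed birth–death tree."""
    if death == 0:
        return 1.0 - np.exp(-birth * t)
    r = birth - death
    return birth * (1.0 - np.exp(-r * t)) / (birth - death * np.exp(-r * t))


def _depth_quantile(u: np.ndarray, t0: float, birth: float, death: float) -> np.ndarray:
    """Inverse CDF of node depth conditioned on depth <= t0."""
    v = u * _depth_cdf(np.asarray([t0]), birth, death)[0]
    if death == 0:
        return -np.log(1.0 - v) / birth
    r = birth - death
    x = birth * (v - 1.0) / (v * death - birth)  # e^{-r t}
    return -np.log(x) / r


def sample_timetree(
    n_taxa: int,
    birth: float,
    death: float,
    root_age: float,
    seed: int | np.random.Generator = 0,
) -> dendropy.Tree:
    """Ultrametric birth–death tree conditioned on taxon count and root age.

    Uses the coalescent-point-process construction for reconstructed
    constant-rate birth–death trees: the ``n - 1`` inter-leaf node depths
    are i.i.d. draws from the birth–death depth distribution truncated at
    the root age, with the root depth itself placed uniformly among them.
    Every leaf sits at depth 0, so each leaf-to-root path spans exactly
    ``root_age`` Ma.
    """
    if not (birth > death >= 0):
        raise ValidationError("need birth > death >= 0")
    if not root_age > 0:
        raise ValidationError("root_age must be positive")
    if n_taxa < 2:
        raise ValidationError("need at least 2 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depths = list(_depth_quantile(rng.random(n_taxa - 2), root_age, birth, death))
    root_slot = int(rng.integers(0, n_taxa - 1))
    depths.insert(root_slot, root_age)

    labels = [f"t{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(lo: int, hi: int) -> dendropy.Node:
        # leaves lo..hi separated by depths[lo..hi-1]
        if lo == hi:
            node = dendropy.Node()
            node.taxon = tns.get_taxon(labels[lo])
            node.age = 0.0
            return node
        split = max(range(lo, hi), key=lambda i: depths[i])
        node = dendropy.Node()
        node.age = depths[split]
        for child in (build(lo, split), build(split + 1, hi)):
            node.add_child(child)
            child.edge.length = node.age - child.age
        return node

    tree.seed_node = build(0, n_taxa - 1)
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# sequence simulation along the tree

def build_invariant_mask(chain: str, length: int) -> dict[int, str]:
    """Frozen sites for one chain: Gly frame, K/R boundaries, discriminator.

    Returns a map from 0-based site index to mandated residue.  The Gly and
    boundary pattern follows the bundled helical scaffold; α1 and α3
    additionally freeze the full 17-residue T32/33 window (K- and
    Q-signature respectively) when the chain is long enough to contain it.
    """
    scaffold = refs._helical_scaffold(length)
    mask: dict[int, str] = {}
    for p in range(1, length + 1):
        if p % 3 == 1:
            mask[p - 1] = "G"
        elif scaffold[p - 1] in "KR":
            mask[p - 1] = scaffold[p - 1]
    window = {"alpha1": refs.ALPHA1_T33_WINDOW, "alpha3": refs.ALPHA3_T33_WINDOW}.get(chain)
    if window is not None and length >= refs.T33_WINDOW_END:
        for offset, residue in enumerate(window):
            mask[refs.T33_WINDOW_START - 1 + offset] = residue
    return mask


@dataclass
class SubstitutionEvent:
    """One logged substitution on one edge."""

    chain: str
    edge_head: str  # label of the node below the edge
    site: int  # 0-based within the chain
    from_aa: str
    to_aa: str
    time_offset: float  # Ma from the start (top) of the edge


def _node_label(node: dendropy.Node, counter: dict) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if id(node) not in counter:
        counter[id(node)] = f"internal_{len(counter)}"
    return counter[id(node)]


def _draw_root(length: int, mask: dict[int, str], model: SubstitutionModel,
               rng: np.random.Generator) -> np.ndarray:
    seq = rng.choice(20, size=length, p=model.frequencies)
    for pos, aa in mask.items():
        if aa not in _AA_INDEX:
            raise ValidationError(f"mask mandates non-standard residue {aa!r}")
        seq[pos] = _AA_INDEX[aa]
    return seq


def _evolve_branch(
    seq: np.ndarray,
    free_sites: np.ndarray,
    subs_length: float,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> list[tuple[int, int, int, float]]:
    """Jump-chain CTMC simulation; returns (site, from, to, frac_time) events."""
    events: list[tuple[int, int, int, float]] = []
    if subs_length <= 0 or len(free_sites) == 0:
        return events
    Q = model.rate_matrix
    exit_rates = -np.diag(Q)
    jump_probs = Q / exit_rates[:, None]
    np.fill_diagonal(jump_probs, 0.0)
    remaining = np.full(len(free_sites), subs_length)
    active = np.arange(len(free_sites))
    while len(active):
        states = seq[free_sites[active]]
        waits = rng.exponential(1.0 / exit_rates[states])
        hit = waits < remaining[active]
        for local, w in zip(active[hit], waits[hit]):
            site = free_sites[local]
            old = seq[site]
            new = rng.choice(20, p=jump_probs[old])
            elapsed = subs_length - (remaining[local] - w)
            events.append((int(site), int(old), int(new), float(elapsed / subs_length)))
            seq[site] = new
        remaining[active] -= waits
        active = active[hit]
    return events


def simulate_chain(
    tree: dendropy.Tree,
    chain: str,
    length: int,
    site_rate: float,
    model: SubstitutionModel | None = None,
    invariant_mask: dict[int, str] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, str], np.ndarray, list[SubstitutionEvent]]:
    """Evolve one chain along a chronogram under the substitution model.

    The root sequence is drawn from the stationary frequencies with masked
    positions set to their mandated residues; masked sites never change.
    Branch lengths in expected substitutions are ``site_rate × duration``.
    Returns ``(tip_sequences, root_sequence_codes, events)``.
    """
    model = model or dayhoff_model()
    mask = build_invariant_mask(chain, length) if invariant_mask is None else invariant_mask
    for pos in mask:
        if not 0 <= pos < length:
            raise ValidationError(f"mask position {pos} outside chain of length {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root_seq = _draw_root(length, mask, model, rng)
    free_sites = np.array(sorted(set(range(length)) - set(mask)), dtype=int)

    tips: dict[str, str] = {}
    events: list[SubstitutionEvent] = []
    counter: dict = {}
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        seq = parent_seq.copy()
        duration = node.edge.length or 0.0
        branch_events = _evolve_branch(seq, free_sites, site_rate * duration, model, rng)
        head = _node_label(node, counter)
        for site, old, new, frac in branch_events:
            events.append(
                SubstitutionEvent(
                    chain=chain, edge_head=head, site=site,
                    from_aa=MODEL_ORDER[old], to_aa=MODEL_ORDER[new],
                    time_offset=frac * duration,
                )
            )
        seqs[id(node)] = seq
        if node.is_leaf():
            tips[node.taxon.label] = "".join(MODEL_ORDER[i] for i in seq)
    return tips, root_seq, events


def replay_events(
    tree: dendropy.Tree,
    root_seq: np.ndarray,
    events: list[SubstitutionEvent],
) -> dict[str, str]:
    """Reapply logged substitutions from the root down; returns tip sequences.

    Independent of the simulator's internal state — used to verify that the
    truth channel is consistent with the emitted sequences.
    """
    by_edge: dict[str, list[SubstitutionEvent]] = {}
    for ev in events:
        by_edge.setdefault(ev.edge_head, []).append(ev)
    counter: dict = {}
    tips: dict[str, str] = {}
    seqs = {id(tree.seed_node): np.asarray(root_seq).copy()}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        seq = seqs[id(node.parent_node)].copy()
        head = _node_label(node, counter)
        for ev in sorted(by_edge.get(head, []), key=lambda e: e.time_offset):
            assert MODEL_ORDER[seq[ev.site]] == ev.from_aa
            seq[ev.site] = _AA_INDEX[ev.to_aa]
        seqs[id(node)] = seq
        if node.is_leaf():
            tips[node.taxon.label] = "".join(MODEL_ORDER[i] for i in seq)
    return tips


# ---------------------------------------------------------------------------
# whole datasets

@dataclass
class SimulatedDataset:
    """Synthetic dataset plus the ground truth used to score the pipeline."""

    config: SimulationConfig
    true_tree: dendropy.Tree
    records: list[ChainRecord]
    root_sequences: dict[str, np.ndarray]
    events: dict[str, list[SubstitutionEvent]]
    truth_labels: dict[tuple[str, str, str | None], str]  # (taxon, chain, isoform) -> true chain
    realized_rates: dict[str, float]  # events per free site per Ma

    def tip_sequences(self, chain: str) -> dict[str, str]:
        out = {}
        for rec in self.records:
            if rec.chain == chain and (rec.isoform in (None, "A")):
                out[rec.taxon] = rec.sequence
        return out

    def write(self, outdir) -> dict[str, str]:
        """Write FASTA + Newick + truth TSV; returns written paths."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "chains.fasta"
        with open(fasta, "w") as fh:
            for rec in self.records:
                iso = rec.isoform or ""
                fh.write(f">{rec.taxon}|{rec.chain}|{iso}|helical|{rec.source_id}\n")
                for i in range(0, len(rec.sequence), 80):
                    fh.write(rec.sequence[i : i + 80] + "\n")
        tree_path = outdir / "true_tree.nwk"
        self.true_tree.write(path=str(tree_path), schema="newick")
        truth = outdir / "truth.tsv"
        with open(truth, "w") as fh:
            fh.write("taxon\tisoform\tchain\n")
            for (taxon, _, iso), chain in sorted(
                self.truth_labels.items(), key=lambda kv: (kv[0][0], kv[0][2] or "", kv[1])
            ):
                fh.write(f"{taxon}\t{iso or ''}\t{chain}\n")
        return {"fasta": str(fasta), "tree": str(tree_path), "truth": str(truth)}


def _mutate_fraction(
    seq: np.ndarray,
    free_sites: np.ndarray,
    fraction_of_length: float,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Substitute ~fraction×length positions (chosen among free sites)."""
    out = seq.copy()
    n_changes = min(int(round(fraction_of_length * len(seq))), len(free_sites))
    sites = rng.choice(free_sites, size=n_changes, replace=False)
    for site in sites:
        probs = model.frequencies.copy()
        probs[out[site]] = 0.0
        out[site] = rng.choice(20, p=probs / probs.sum())
    return out


def make_dataset(config: SimulationConfig, model: SubstitutionModel | None = None) -> SimulatedDataset:
    """Simulate a full dataset: three chains, α3 loss, tetraploid isoforms.

    α1, α2 and α3 evolve on the same chronogram at their configured rates.
    The α3 root sequence is the α1 root mutated at
    ``alpha3_root_divergence`` of its sites (the two chains are a gene
    duplication pair), with each chain's own discriminator signature frozen.
    A seeded subset of ``round(missing_fraction × n)`` taxa lose α3; a
    seeded subset of tetraploid taxa gain a B isoform of every carried
    chain, diverged from the A copy by a target drawn uniformly from the
    configured band.
    """
    model = model or dayhoff_model()
    rng = np.random.default_rng(config.seed)
    if config.tree_newick is not None:
        tree = dendropy.Tree.get(data=config.tree_newick, schema="newick",
                                 preserve_underscores=True)
    else:
        tree = sample_timetree(
            config.n_taxa, config.birth_rate, config.death_rate, config.root_age, rng
        )
    taxa = sorted({lf.taxon.label for lf in tree.leaf_node_iter()})
    n = len(taxa)
    total_duration = sum(e.length or 0.0 for e in tree.edges())

    n_missing = int(round(config.alpha3_missing_fraction * n))
    alpha3_missing = set(rng.choice(taxa, size=n_missing, replace=False))
    n_tetra = int(round(config.tetraploid_fraction * n))
    tetraploids = set(rng.choice(taxa, size=n_tetra, replace=False))

    records: list[ChainRecord] = []
    root_sequences: dict[str, np.ndarray] = {}
    all_events: dict[str, list[SubstitutionEvent]] = {}
    truth_labels: dict[tuple[str, str, str | None], str] = {}
    realized: dict[str, float] = {}

    masks = {
        chain: build_invariant_mask(chain, config.chain_lengths[chain])
        for chain in CHAIN_ORDER
    }
    # The α1 root is anchored to the bundled reference (real chains are
    # homologous to it, which is what makes alignment-based window transfer
    # work on pipeline output); α3 descends from a duplication of α1.
    roots: dict[str, np.ndarray] = {}
    L1 = config.chain_lengths["alpha1"]
    if L1 == len(refs.alpha1_helical_reference()):
        roots["alpha1"] = np.array(
            [_AA_INDEX[c] for c in refs.alpha1_helical_reference()]
        )
    else:
        roots["alpha1"] = _draw_root(L1, masks["alpha1"], model, rng)
    roots["alpha2"] = _draw_root(config.chain_lengths["alpha2"], masks["alpha2"], model, rng)
    L3 = config.chain_lengths["alpha3"]
    a3 = np.empty(L3, dtype=roots["alpha1"].dtype)
    shared = min(L1, L3)
    a3[:shared] = roots["alpha1"][:shared]
    if L3 > shared:
        a3[shared:] = rng.choice(20, size=L3 - shared, p=model.frequencies)
    free3 = np.array(sorted(set(range(L3)) - set(masks["alpha3"])), dtype=int)
    a3 = _mutate_fraction(a3, free3, config.alpha3_root_divergence, model, rng)
    for pos, aa in masks["alpha3"].items():
        a3[pos] = _AA_INDEX[aa]
    roots["alpha3"] = a3

    for chain in CHAIN_ORDER:
        length = config.chain_lengths[chain]
        mask = masks[chain]
        free_sites = np.array(sorted(set(range(length)) - set(mask)), dtype=int)
        tips: dict[str, str] = {}
        events: list[SubstitutionEvent] = []
        counter: dict = {}
        seqs = {id(tree.seed_node): roots[chain].copy()}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            seq = seqs[id(node.parent_node)].copy()
            duration = node.edge.length or 0.0
            branch_events = _evolve_branch(
                seq, free_sites, config.site_rates[chain] * duration, model, rng
            )
            head = _node_label(node, counter)
            for site, old, new, frac in branch_events:
                events.append(
                    SubstitutionEvent(
                        chain=chain, edge_head=head, site=site,
                        from_aa=MODEL_ORDER[old], to_aa=MODEL_ORDER[new],
                        time_offset=frac * duration,
                    )
                )
            seqs[id(node)] = seq
            if node.is_leaf():
                tips[node.taxon.label] = "".join(MODEL_ORDER[i] for i in seq)
        root_sequences[chain] = roots[chain]
        all_events[chain] = events
        denom = max(len(free_sites), 1) * max(total_duration, 1e-12)
        realized[chain] = len(events) / denom

        for taxon in taxa:
            if chain == "alpha3" and taxon in alpha3_missing:
                continue
            is_tetra = taxon in tetraploids
            iso_a = "A" if is_tetra else None
            rec = ChainRecord(
                taxon=taxon, chain=chain, sequence=tips[taxon], isoform=iso_a,
                region="helical", source_id="simulated", relaxed_length=True,
            )
            records.append(rec)
            truth_labels[(taxon, chain, iso_a)] = chain
            if is_tetra:
                target = rng.uniform(*config.isoform_divergence)
                codes = np.array([_AA_INDEX[c] for c in tips[taxon]])
                b_codes = _mutate_fraction(codes, free_sites, target, model, rng)
                records.append(
                    ChainRecord(
                        taxon=taxon, chain=chain,
                        sequence="".join(MODEL_ORDER[i] for i in b_codes),
                        isoform="B", region="helical",
                        source_id="simulated", relaxed_length=True,
                    )
                )
                truth_labels[(taxon, chain, "B")] = chain

    return SimulatedDataset(
        config=config,
        true_tree=tree,
        records=records,
        root_sequences=root_sequences,
        events=all_events,
        truth_labels=truth_labels,
        realized_rates=realized,
    )


# ---------------------------------------------------------------------------
# tree-sample perturbation (stand-in for posterior samples)

def _nni_once(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    internal_edges = [
        e for e in tree.preorder_edge_iter()
        if e.head_node is not None and e.tail_node is not None
        and not e.head_node.is_leaf()
    ]
    if not internal_edges:
        raise ValidationError("tree has no internal edges for NNI")
    edge = internal_edges[int(rng.integers(len(internal_edges)))]
    child, parent = edge.head_node, edge.tail_node
    siblings = [c for c in parent.child_nodes() if c is not child]
    grandchildren = child.child_nodes()
    if not siblings or len(grandchildren) < 2:
        raise ValidationError("NNI requires a binary tree")
    sib = siblings[int(rng.integers(len(siblings)))]
    gc = grandchildren[int(rng.integers(len(grandchildren)))]
    parent.remove_child(sib)
    child.remove_child(gc)
    parent.add_child(gc)
    child.add_child(sib)


def perturb_tree_sample(
    tree: dendropy.Tree,
    n_trees: int,
    moves_per_tree: int,
    seed: int = 0,
) -> list[dendropy.Tree]:
    """Clouds of trees around a source topology via random NNI moves.

    Each output tree is an independent copy of the input after
    ``moves_per_tree`` random nearest-neighbour interchanges; zero moves
    yields exact copies.  The expected quartet distance to the source grows
    with the number of moves, so two clouds generated from distinct sources
    mimic two posterior samples concentrating on different topologies.
    """
    for node in tree.preorder_internal_node_iter():
        n_children = len(node.child_nodes())
        if n_children > 2:
            raise ValidationError("perturbation requires a binary input tree")
    if moves_per_tree < 0:
        raise ValidationError("moves_per_tree must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        clone = dendropy.Tree.get(
            data=tree.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=tree.taxon_namespace,
            preserve_underscores=True,
        )
        for _ in range(moves_per_tree):
            _nni_once(clone, rng)
        out.append(clone)
    return out
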