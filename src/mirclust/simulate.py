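"""Synthetic microRNA-repertoire evolution along a species tree.

Events are sampled per branch (Gillespie-style, rates per unit branch
length) and every sampled quantity is recorded in the event log, so that
replaying the log from the root state reproduces the extant genomes
exactly.  Per-branch random streams are keyed by (seed, branch index) so a
subtree's events do not depend on the order other subtrees are visited.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import DEFAULT_MAX_GAP, Cluster, call_clusters
from .model import ExpressionMatrix, HomologyMap, MicroRNALocus, SpeciesPhylogeny
from .origin import OriginCall, Source, classify_cluster_origin

EVENT_TYPES = (
    "birth_in_transcript",
    "birth_intergenic",
    "duplication",
    "loss",
    "cluster_loss",
    "translocation",
)


@dataclass
class SimulationParams:
    """Rates are per unit branch length; placement offsets are nt."""

    rate_new_hairpin_in_transcript: float = 0.04   # per existing locus
    rate_intergenic_birth: float = 0.02            # per genome
    rate_tandem_duplication: float = 0.04          # per locus
    rate_loss_mirna: float = 0.01                  # per singleton locus
    rate_loss_cluster: float = 0.005               # per cluster (lost whole)
    rate_translocation: float = 0.0                # per locus
    tandem_offset: tuple[int, int] = (50, 500)     # uniform nt gap to the copy
    n_chromosomes: int = 4
    chromosome_length: int = 2_000_000
    n_root_loci: int = 6
    max_gap: int = DEFAULT_MAX_GAP
    expression_rho: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rate_new_hairpin_in_transcript",
            "rate_intergenic_birth",
            "rate_tandem_duplication",
            "rate_loss_mirna",
            "rate_loss_cluster",
            "rate_translocation",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.expression_rho <= 1:
            raise ValueError("expression_rho must be in [0, 1]")


@dataclass(frozen=True)
class SimLocus:
    """Internal simulator locus; ``origin_event`` tags how it was created."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    origin_event: str          # root / birth_in_transcript / birth_intergenic / duplication
    origin_branch: str         # child-node name of the branch it arose on
    origin_time: float
    parent_id: str | None = None


@dataclass(frozen=True)
class Event:
    branch: str                # child-node name of the branch
    time: float
    event_type: str
    affected: tuple[str, ...]  # locus ids removed (losses) or created
    parent_id: str | None = None
    new_locus: SimLocus | None = None
    new_position: tuple[str, int, int, str] | None = None  # translocation target


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)

    def append(self, event: Event) -> None:
        self.events.append(event)

    def on_branch(self, branch: str) -> list[Event]:
        return [e for e in self.events if e.branch == branch]

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "branch": e.branch,
                "time": e.time,
                "event_type": e.event_type,
                "affected": ",".join(e.affected),
                "parent_id": e.parent_id or "",
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows, columns=["branch", "time", "event_type", "affected", "parent_id"]
        )


@dataclass
class SimulationResult:
    root_state: list[SimLocus]
    species_loci: dict[str, list[MicroRNALocus]]
    species_states: dict[str, list[SimLocus]]
    event_log: EventLog
    tree: SpeciesPhylogeny
    params: SimulationParams

    def homology_map(self) -> HomologyMap:
        """Exact homology over all extant species (families are ground truth)."""
        hom = HomologyMap(self.tree.species)
        for loci in self.species_loci.values():
            for locus in loci:
                hom.add(locus)
        return hom


def _root_repertoire(params: SimulationParams) -> list[SimLocus]:
    loci = []
    spacing = params.chromosome_length // (params.n_root_loci + 1)
    for i in range(params.n_root_loci):
        chrom = f"chr{i % params.n_chromosomes + 1}"
        start = spacing * (i // params.n_chromosomes + 1) + i * 301_000 + 1
        loci.append(
            SimLocus(
                locus_id=f"anc{i}",
                chrom=chrom,
                start=start,
                end=start + 89,
                strand="+" if i % 2 == 0 else "-",
                family=f"fam-anc{i}",
                origin_event="root",
                origin_branch="root",
                origin_time=0.0,
            )
        )
    return loci


def _state_clusters(state: Sequence[SimLocus], max_gap: int) -> list[list[SimLocus]]:
    """Chains of >= 2 loci at gap < max_gap (same chrom and strand)."""
    groups: dict[tuple[str, str], list[SimLocus]] = {}
    for locus in state:
        groups.setdefault((locus.chrom, locus.strand), []).append(locus)
    clusters = []
    for key in sorted(groups):
        run: list[SimLocus] = []
        for locus in sorted(groups[key], key=lambda l: l.start):
            if run and max(0, locus.start - run[-1].end - 1) < max_gap:
                run.append(locus)
            else:
                if len(run) >= 2:
                    clusters.append(run)
                run = [locus]
        if len(run) >= 2:
            clusters.append(run)
    return clusters


def apply_event(state: list[SimLocus], event: Event) -> list[SimLocus]:
    """Pure state transition used both by the simulator and by replay."""
    if event.event_type in ("birth_in_transcript", "birth_intergenic", "duplication"):
        assert event.new_locus is not None
        return state + [event.new_locus]
    if event.event_type in ("loss", "cluster_loss"):
        gone = set(event.affected)
        return [l for l in state if l.locus_id not in gone]
    if event.event_type == "translocation":
        assert event.new_position is not None
        chrom, start, end, strand = event.new_position
        (locus_id,) = event.affected
        return [
            replace(l, chrom=chrom, start=start, end=end, strand=strand)
            if l.locus_id == locus_id
            else l
            for l in state
        ]
    raise ValueError(f"unknown event type {event.event_type!r}")


def _simulate_branch(
    state: list[SimLocus],
    branch: str,
    length: float,
    params: SimulationParams,
    rng: np.random.Generator,
    log: EventLog,
) -> list[SimLocus]:
    t = 0.0
    counter = 0
    while True:
        n = len(state)
        clusters = _state_clusters(state, params.max_gap)
        # single-microRNA loss hits unclustered loci; clustered microRNAs
        # are lost as whole clusters
        clustered_ids = {l.locus_id for c in clusters for l in c}
        singletons = [l for l in state if l.locus_id not in clustered_ids]
        rates = np.array(
            [
                params.rate_new_hairpin_in_transcript * n,
                params.rate_intergenic_birth,
                params.rate_tandem_duplication * n,
                params.rate_loss_mirna * len(singletons),
                params.rate_loss_cluster * len(clusters),
                params.rate_translocation * n,
            ]
        )
        total = rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= length:
            break
        kind = EVENT_TYPES[rng.choice(len(rates), p=rates / total)]
        counter += 1
        event = _draw_event(
            kind, state, clusters, singletons, branch, t, counter, params, rng
        )
        if event is None:
            continue
        log.append(event)
        state = apply_event(state, event)
    return state


def _draw_event(
    kind: str,
    state: list[SimLocus],
    clusters: list[list[SimLocus]],
    singletons: list[SimLocus],
    branch: str,
    t: float,
    counter: int,
    params: SimulationParams,
    rng: np.random.Generator,
) -> Event | None:
    def random_position() -> tuple[str, int, int, str]:
        chrom = f"chr{rng.integers(1, params.n_chromosomes + 1)}"
        start = int(rng.integers(1, params.chromosome_length))
        strand = "+" if rng.random() < 0.5 else "-"
        return chrom, start, start + 89, strand

    if kind == "birth_intergenic":
        chrom, start, end, strand = random_position()
        locus = SimLocus(
            locus_id=f"{branch}.{counter}",
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            family=f"fam-{branch}.{counter}",
            origin_event=kind,
            origin_branch=branch,
            origin_time=t,
        )
        return Event(branch, t, kind, (locus.locus_id,), new_locus=locus)

    if kind in ("birth_in_transcript", "duplication"):
        parent = state[rng.integers(len(state))]
        offset = int(rng.integers(params.tandem_offset[0], params.tandem_offset[1] + 1))
        start = parent.end + 1 + offset
        family = (
            parent.family if kind == "duplication" else f"fam-{branch}.{counter}"
        )
        locus = SimLocus(
            locus_id=f"{branch}.{counter}",
            chrom=parent.chrom,
            start=start,
            end=start + 89,
            strand=parent.strand,
            family=family,
            origin_event=kind,
            origin_branch=branch,
            origin_time=t,
            parent_id=parent.locus_id,
        )
        return Event(
            branch, t, kind, (locus.locus_id,), parent_id=parent.locus_id,
            new_locus=locus,
        )

    if kind == "loss":
        victim = singletons[rng.integers(len(singletons))]
        return Event(branch, t, kind, (victim.locus_id,))

    if kind == "cluster_loss":
        cluster = clusters[rng.integers(len(clusters))]
        return Event(branch, t, kind, tuple(l.locus_id for l in cluster))

    if kind == "translocation":
        victim = state[rng.integers(len(state))]
        return Event(
            branch, t, kind, (victim.locus_id,), new_position=random_position()
        )

    raise ValueError(kind)


def simulate(
    tree: SpeciesPhylogeny,
    params: SimulationParams,
    root_state: Sequence[SimLocus] | None = None,
) -> SimulationResult:
    """Evolve a repertoire down the tree; returns extant loci + event log."""
    root = list(root_state) if root_state is not None else _root_repertoire(params)
    log = EventLog()
    states: dict[str, list[SimLocus]] = {tree.root: list(root)}
    branch_index = {child: i for i, (_, child, _) in enumerate(tree.branches())}
    for parent, child, length in tree.branches():
        rng = np.random.default_rng(
            np.random.SeedSequence((params.seed, branch_index[child]))
        )
        states[child] = _simulate_branch(
            list(states[parent]), child, length, params, rng, log
        )
    species_states = {s: states[s] for s in tree.species}
    species_loci = {
        s: [_to_locus(l, s) for l in sorted(st, key=lambda l: (l.chrom, l.start))]
        for s, st in species_states.items()
    }
    return SimulationResult(root, species_loci, species_states, log, tree, params)


def _to_locus(sim: SimLocus, species: str) -> MicroRNALocus:
    return MicroRNALocus(
        mirna_id=f"{species}:{sim.locus_id}",
        species_id=species,
        chrom=sim.chrom,
        start=sim.start,
        end=sim.end,
        strand=sim.strand,
        annotation_family=sim.family,
        phylo_family=sim.family,
    )


def replay(
    tree: SpeciesPhylogeny,
    root_state: Sequence[SimLocus],
    log: EventLog,
) -> dict[str, list[SimLocus]]:
    """Re-derive extant states from the root state and the event log alone."""
    states: dict[str, list[SimLocus]] = {tree.root: list(root_state)}
    for parent, child, _length in tree.branches():
        state = list(states[parent])
        for event in sorted(log.on_branch(child), key=lambda e: e.time):
            state = apply_event(state, event)
        states[child] = state
    return {s: states[s] for s in tree.species}


# -- expression ------------------------------------------------------------


def generate_expression(
    loci: Sequence[MicroRNALocus],
    clusters: Sequence[Cluster],
    rho: float,
    n_samples: int,
    seed: int,
    base_mean: float = 1000.0,
    log_sd: float = 1.2,
    dispersion: float = 0.1,
) -> ExpressionMatrix:
    """Negative-binomial counts with a shared latent profile per cluster.

    Each cluster draws one latent per-sample log-profile; each member mixes
    it with a private profile at weight sqrt(rho) (so the latent log-scale
    correlation of two members of one cluster is rho).  Singletons are
    fully independent.  dispersion -> 0 recovers Poisson noise.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cluster_of = {m: c.cluster_id for c in clusters for m in c.members}
    latents = {
        c.cluster_id: rng.normal(size=n_samples) for c in clusters
    }
    rows = {}
    for locus in loci:
        private = rng.normal(size=n_samples)
        if locus.mirna_id in cluster_of:
            shared = latents[cluster_of[locus.mirna_id]]
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * private
        else:
            z = private
        mean = base_mean * np.exp(log_sd * z - 0.5 * log_sd**2)
        if dispersion > 0:
            lam = rng.gamma(1.0 / dispersion, dispersion * mean)
        else:
            lam = mean
        rows[locus.mirna_id] = rng.poisson(lam)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"sample{j + 1}" for j in range(n_samples)]
    return ExpressionMatrix(df)


# -- recovery experiment ---------------------------------------------------

_TRUTH_CLASS = {
    "duplication": Source.DUPLICATION,
    "birth_in_transcript": Source.NEW_HAIRPIN,
    "birth_intergenic": Source.NEW_HAIRPIN,
    "root": Source.UNKNOWN,
    "translocation": Source.FUSION,
}


def true_founding_event(
    cluster: Cluster,
    states: dict[str, SimLocus],
    tree: SpeciesPhylogeny,
    focal: str,
) -> Source:
    """Ground-truth founding event of an extant cluster.

    Members are ordered by creation time along the root-to-focal path; the
    second member's creating event is the one that first made the region
    polycistronic.  (Losses can erase the true founders, in which case the
    truth reported here is the founding event among surviving members --
    the same masking that limits the inference method itself.)
    """
    focal_path = tree.path_to_root(focal)
    rank = {node: i for i, node in enumerate(reversed(focal_path))}

    def creation_key(locus_id: str):
        sim = states[locus_id]
        branch_rank = rank.get(sim.origin_branch, -1)  # root before any branch
        return (branch_rank, sim.origin_time)

    ordered = sorted(
        (m.split(":", 1)[1] for m in cluster.members), key=creation_key
    )
    second = states[ordered[1]]
    return _TRUTH_CLASS[second.origin_event]


@dataclass
class RecoveryResult:
    confusion: pd.DataFrame      # rows = truth, cols = call, cells = counts
    n_clusters: int

    def recall(self, source: Source) -> float:
        row = self.confusion.loc[source.value]
        total = row.sum()
        return float(row[source.value] / total) if total else float("nan")

    def precision(self, source: Source) -> float:
        col = self.confusion[source.value]
        total = col.sum()
        return float(col[source.value] / total) if total else float("nan")


def recovery_experiment(
    tree: SpeciesPhylogeny,
    params: SimulationParams,
    n_reps: int,
    seed: int,
    focal_species: str | None = None,
) -> RecoveryResult:
    """Simulate, re-detect clusters, classify origins, score against truth."""
    focal = focal_species or tree.species[0]
    labels = [s.value for s in Source]
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    n_clusters = 0
    for rep in range(n_reps):
        rep_params = replace(params, seed=seed * 100_003 + rep)
        result = simulate(tree, rep_params)
        loci = result.species_loci[focal]
        clusters = call_clusters(loci, max_gap=params.max_gap)
        if not clusters:
            continue
        hom = result.homology_map()
        loci_by_id = {l.mirna_id: l for l in loci}
        states = {l.locus_id: l for l in result.species_states[focal]}
        for cluster in clusters:
            truth = true_founding_event(cluster, states, tree, focal)
            call = classify_cluster_origin(
                cluster, loci_by_id, hom, tree, max_gap=params.max_gap
            )
            confusion.loc[truth.value, call.source.value] += 1
            n_clusters += 1
    return RecoveryResult(confusion, n_clusters)
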