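"""Ground-truthed synthetic inputs: a clade of near-identical genomes evolved
from a common ancestor, and strand-specific coverage tracks with an early/late
temporal program.

The default specs emulate the regime the analysis targets: four ~52-kb ingroup
genomes at 98-99% identity plus one outgroup, ~10-30 small indels (geometric
sizes, mean 2 bp — most observed indels in this regime are 1-2 bp) and
~500-1000 pairwise substitutions, one scripted ~3.6-kb deletion flanked by a
3-bp direct repeat on a named branch, two divergently transcribed gene arms
with planted 13-bp operator-like sites in one orientation, and coverage with
an early leftwards program, a late rightwards program and a dominant stable
~500-nt non-coding transcript downstream of the early promoter.

Every event is logged with exact ancestor coordinates; replaying the log
reproduces the leaf genomes byte-for-byte, which is what recovery tests and
the acceptance checks compare against.  Substitution and indel events are
drawn per branch (Poisson in the branch length) but placed in ancestor
coordinates with rejection so that no two footprints overlap: the generated
clades are homoplasy-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_utils import GeneFeature, GenomeRecord, Interval, write_bed_features, write_fasta
from .phylo import Node, Tree
from .transcripts import CoverageTrack, PromoterSite, write_bedgraph

DEFAULT_TREE = ("((((D29:0.005,StarStuff:0.005):0.0025,Pomar16:0.005):0.0025,"
                "Kerberos:0.006):0.011,Serenity:0.011);")


class SimulationError(ValueError):
    pass


@dataclass
class EvolutionSpec:
    """Parameters of the genome-evolution simulator (defaults = study regime)."""

    ancestor_length: int = 52_000
    gc: float = 0.64                       # mycobacteriophage-like GC content
    tree_newick: str = DEFAULT_TREE
    outgroup: str = "Serenity"
    sub_rate: float = 1.0                  # substitutions/site per unit branch length
    indel_rate: float = 0.015              # indels/site per unit branch length
    indel_mean: float = 2.0                # geometric size distribution mean (bp)
    large_deletion_length: int = 3650
    large_deletion_repeat: str = "CCA"
    large_deletion_branch: str = "D29"
    n_motif_sites: int = 24
    motif_consensus: str = "GGTGG[CA]TGTCAAG"
    motif_orientation_bias: float = 1.0    # fraction co-oriented with transcription
    seed: int = 0

    def __post_init__(self):
        if min(self.sub_rate, self.indel_rate) < 0:
            raise SimulationError("rates must be >= 0")
        if self.ancestor_length < 12_000:
            raise SimulationError("ancestor too short for the planted layout")
        if self.large_deletion_length + 3000 > self.ancestor_length:
            raise SimulationError("planted deletion does not fit the ancestor")


@dataclass
class SimEvent:
    event_type: str                        # substitution | insertion | deletion | large_deletion
    branch: str                            # phylo branch id (sorted leaf set)
    anc_start: int                         # 1-based ancestor coordinates
    anc_end: int
    length: int
    seq: str = ""                          # inserted or deleted sequence, or "X>Y"
    repeat: str = ""                       # direct-repeat context, if any

    @property
    def is_indel(self) -> bool:
        return self.event_type in ("insertion", "deletion", "large_deletion")


@dataclass
class EventLog:
    events: list[SimEvent] = field(default_factory=list)

    def indels(self, min_len: int = 1) -> list[SimEvent]:
        return [e for e in self.events if e.is_indel and e.length >= min_len]

    def on_branch(self, branch: str) -> list[SimEvent]:
        return [e for e in self.events if e.branch == branch]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.events])

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# type\tbranch\tanc_start\tanc_end\tlength\tseq\trepeat\n")
            for e in self.events:
                fh.write(f"{e.event_type}\t{e.branch}\t{e.anc_start}\t{e.anc_end}"
                         f"\t{e.length}\t{e.seq or '.'}\t{e.repeat or '.'}\n")


@dataclass
class AncestorLayout:
    """The planted ancestor: genome, annotation and ground-truth landmarks."""

    genome: GenomeRecord
    motif_sites: list[Interval]            # stranded 13-bp sites, operator last
    deletion_interval: Interval            # repeat-flanked substrate, 1-based
    repressor: GeneFeature
    promoters: list[PromoterSite]
    terminators: list[tuple[int, str, float]]   # (position, strand, read-through)
    srna_interval: Interval                # stable non-coding transcript (minus strand)
    srna_ramp: int                         # 5' under-representation length (bp)
    expected_classes: dict[str, str]       # gene id -> early/late (planted program)

    @property
    def features(self) -> list[GeneFeature]:
        return self.genome.features


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _plant(seq: list[str], start0: int, text: str) -> None:
    seq[start0: start0 + len(text)] = list(text)


def make_ancestor(spec: EvolutionSpec,
                  rng: Optional[np.random.Generator] = None) -> AncestorLayout:
    """Random ancestor genome with the planted study layout.

    Two divergently organized gene arms (rightwards left arm of late genes,
    leftwards right arm of early genes), a repeat-flanked deletion substrate
    containing the repressor analog, operator-like sites in intergenic gaps
    co-oriented with transcription, an early leftwards promoter near the right
    end with a ~500-bp non-coding region downstream of it, and a late
    rightwards promoter near the left end.  Deterministic under the spec seed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    L = spec.ancestor_length
    seq = list(_random_seq(rng, L, spec.gc))

    tss_left = L - 750
    srna = Interval(tss_left - 499, tss_left, "-")
    operator = Interval(tss_left - 6, tss_left + 6, "-")
    del_end = tss_left - 1100
    del_start = del_end - spec.large_deletion_length + 1
    deletion = Interval(del_start, del_end)

    # gene arms ------------------------------------------------------------
    features: list[GeneFeature] = []
    gaps: list[tuple[int, int, str]] = []   # intergenic (start, end, unit strand)

    def fill_arm(a: int, b: int, strand: str, prefix: str) -> None:
        cursor = a
        i = 1
        while True:
            glen = int(rng.integers(600, 1000))
            if cursor + glen - 1 > b:
                break
            features.append(GeneFeature(f"{prefix}{i}", cursor, cursor + glen - 1,
                                        strand))
            gap = int(rng.integers(60, 120))
            gaps.append((cursor + glen, min(cursor + glen + gap - 1, b), strand))
            cursor += glen + gap
            i += 1

    left_arm_end = int(0.40 * L)
    fill_arm(300, left_arm_end, "+", "L")
    mid_start = left_arm_end + 400
    features.append(GeneFeature("M1", mid_start, mid_start + 900, "+",
                                product="integrase analog"))
    fill_arm(int(0.45 * L), tss_left - 560, "-", "R")
    # guarantee a retained gene between the deletion substrate and the
    # non-coding region (the genome keeps a gene right of the deletion), so
    # the stable-transcript region is never flanked by the repressor unit
    if not any(f.strand == "-" and f.start > del_end for f in features):
        gstart = del_end + 80
        gend = min(gstart + 800, tss_left - 620)
        features.append(GeneFeature("Rr", gstart, gend, "-"))
        if tss_left - 560 - gend >= 20:
            gaps.append((gend + 1, tss_left - 560, "-"))

    inside = [f for f in features if deletion.contains(f.start)
              and deletion.contains(f.end)]
    if not inside:
        raise SimulationError("no gene fits inside the deletion substrate")
    repressor = max(inside, key=lambda f: f.end)
    repressor.product = "immunity repressor analog"

    # direct repeats flanking the deletion substrate ------------------------
    rep = spec.large_deletion_repeat.upper()
    r = len(rep)
    s0, e0 = del_start - 1, del_end            # 0-based: deletion is [s0, e0)
    _plant(seq, s0, rep)
    _plant(seq, e0, rep)
    # forbid accidental extension of the junction ambiguity on either side
    if seq[s0 - 1] == seq[e0 - 1]:
        seq[s0 - 1] = "G" if seq[e0 - 1] != "G" else "C"
    if seq[s0 + r] == seq[e0 + r]:
        seq[s0 + r] = "G" if seq[e0 + r] != "G" else "C"

    # motif sites ------------------------------------------------------------
    from .motifs import parse_consensus
    pattern = parse_consensus(spec.motif_consensus)
    mlen = len(pattern)

    def site_text() -> str:
        return "".join(sorted(p)[int(rng.integers(len(p)))]
                       for p in pattern.positions)

    usable = [(gs, ge, st) for gs, ge, st in gaps
              if ge - gs + 1 >= mlen + 4
              and not (gs - 5 <= del_start <= ge + 5)
              and not (gs - 5 <= del_end + r + 1 <= ge + 5)]
    inside_gaps = [g for g in usable if deletion.contains(g[0])]
    outside_gaps = [g for g in usable if not deletion.contains(g[0])]
    n_outside = spec.n_motif_sites - 2      # one inside the substrate, one operator
    if len(outside_gaps) < n_outside or not inside_gaps:
        raise SimulationError("not enough intergenic gaps for the motif sites")
    idx = np.linspace(0, len(outside_gaps) - 1, n_outside).astype(int)
    chosen = [outside_gaps[i] for i in idx] + [inside_gaps[len(inside_gaps) // 2]]
    sites: list[Interval] = []
    for gs, ge, st in chosen:
        mid = (gs + ge) // 2 - mlen // 2
        strand = st if rng.random() < spec.motif_orientation_bias else (
            "+" if st == "-" else "-")
        text = site_text()
        if strand == "-":
            from .io_utils import revcomp
            text = revcomp(text)
        _plant(seq, mid - 1, text)
        sites.append(Interval(mid, mid + mlen - 1, strand))
    # the operator overlapping the early promoter
    from .io_utils import revcomp as _rc
    _plant(seq, operator.start - 1, _rc(site_text()))
    sites.append(Interval(operator.start, operator.end, "-"))

    # planted elements must not overlap
    planted = sites + [Interval(del_start, del_start + r - 1),
                       Interval(del_end + 1, del_end + r)]
    planted_sorted = sorted(planted, key=lambda iv: iv.start)
    for a, b in zip(planted_sorted, planted_sorted[1:]):
        if a.overlaps(b):
            raise SimulationError(f"planted elements overlap: {a} / {b}")

    # transcription program ---------------------------------------------------
    p_left = PromoterSite("P_left", tss_left, "-")
    p_right = PromoterSite("P_right", 230, "+")
    p_rep = PromoterSite("P_rep", min(repressor.end + 60, del_end), "-")
    right_arm_sorted = sorted((f for f in features if f.gene_id.startswith("R")),
                              key=lambda f: f.start)
    below = [f for f in right_arm_sorted if f.end < repressor.start]
    # the lysogenic unit reads leftwards through the repressor and the two
    # genes immediately downstream of it, then terminates
    rep_term_pos = below[-2].start - 10 if len(below) >= 3 else repressor.start - 2500
    terminators = [
        (srna.start - 1, "-", 0.10),       # 3' end of the stable transcript
        (left_arm_end + 150, "+", 0.05),   # late-gene terminator
        (rep_term_pos, "-", 0.50),         # leaky end of the lysogenic repressor unit
    ]
    expected = {f.gene_id: ("late" if f.strand == "+" else "early")
                for f in features}

    genome = GenomeRecord(id="ancestor", seq="".join(seq), features=features)
    return AncestorLayout(
        genome=genome, motif_sites=sites, deletion_interval=deletion,
        repressor=repressor, promoters=[p_left, p_right, p_rep],
        terminators=terminators, srna_interval=srna, srna_ramp=30,
        expected_classes=expected,
    )


# ---------------------------------------------------------------------------
# evolution along a tree


def _apply_events(ancestor_seq: str, events: Sequence[SimEvent]) -> str:
    """Apply substitutions then indels (descending ancestor coordinate)."""
    seq = list(ancestor_seq)
    for e in events:
        if e.event_type == "substitution":
            old, new = e.seq.split(">")
            if seq[e.anc_start - 1] != old:
                raise SimulationError(
                    f"event log inconsistent at {e.anc_start}: "
                    f"expected {old}, found {seq[e.anc_start - 1]}")
            seq[e.anc_start - 1] = new
    indels = sorted((e for e in events if e.is_indel),
                    key=lambda e: -e.anc_start)
    for e in indels:
        if e.event_type == "insertion":
            seq[e.anc_start: e.anc_start] = list(e.seq)
        else:
            del seq[e.anc_start - 1: e.anc_end]
    return "".join(seq)


def replay_event_log(ancestor: GenomeRecord, tree: Tree,
                     log: EventLog) -> dict[str, GenomeRecord]:
    """Rebuild every leaf genome from the ancestor and the event log alone."""
    leaves: dict[str, GenomeRecord] = {}
    by_branch: dict[str, list[SimEvent]] = {}
    for e in log.events:
        by_branch.setdefault(e.branch, []).append(e)

    def walk(node: Node, path_events: list[SimEvent]) -> None:
        events = path_events
        if node.parent is not None:
            events = path_events + by_branch.get(tree.branch_id(node), [])
        if node.is_leaf:
            leaves[node.name] = GenomeRecord(
                id=node.name, seq=_apply_events(ancestor.seq, events))
        for c in node.children:
            walk(c, events)

    walk(tree.root, [])
    return leaves


def anc_to_leaf_coord(tree: Tree, log: EventLog, leaf: str,
                      anc_pos: int) -> Optional[int]:
    """Map a 1-based ancestor coordinate to the leaf genome (None if deleted)."""
    path_branches = set()
    node = next(n for n in tree.postorder() if n.is_leaf and n.name == leaf)
    while node.parent is not None:
        path_branches.add(tree.branch_id(node))
        node = node.parent
    offset = 0
    for e in log.events:
        if not e.is_indel or e.branch not in path_branches:
            continue
        if e.event_type == "insertion":
            if e.anc_start < anc_pos:
                offset += e.length
        else:
            if e.anc_end < anc_pos:
                offset -= e.length
            elif e.anc_start <= anc_pos <= e.anc_end:
                return None
    return anc_pos + offset


def evolve_along_tree(ancestor: AncestorLayout, spec: EvolutionSpec,
                      rng: Optional[np.random.Generator] = None,
                      ) -> tuple[dict[str, GenomeRecord], EventLog, Tree]:
    """Evolve the ancestor along the spec tree.

    Substitution/indel counts are Poisson in (rate x length x branch length);
    positions are rejected until footprints are >= 30 bp apart and clear of the
    scripted deletion, so events never overlap and Dollo recovery has an exact
    truth.  Indels are placed only on branches inside the ingroup clade (a
    single outgroup cannot polarize events on its own branch or the stem); the
    scripted repeat-mediated deletion is executed on the named branch.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    tree = Tree.from_newick(spec.tree_newick)
    leaves = set(tree.leaf_names())
    if spec.outgroup not in leaves:
        raise SimulationError(f"outgroup {spec.outgroup!r} not in tree")
    L = len(ancestor.genome.seq)
    anc_seq = ancestor.genome.seq

    branch_nodes = [n for n in tree.postorder() if n.parent is not None]
    ingroup_stem = next((c for c in tree.root.children
                         if spec.outgroup not in tree.leafset(c)), None)
    if ingroup_stem is None:
        raise SimulationError("outgroup is not separated at the root")
    ingroup_ids = {tree.branch_id(n) for n in branch_nodes
                   if n is not ingroup_stem
                   and tree.leafset(n) < tree.leafset(ingroup_stem)}
    if spec.large_deletion_branch is not None:
        target = {tree.branch_id(n) for n in branch_nodes}
        if (spec.large_deletion_branch not in target
                and spec.large_deletion_branch not in leaves):
            raise SimulationError(
                f"deletion branch {spec.large_deletion_branch!r} not in tree")

    log = EventLog()
    footprints: list[tuple[int, int]] = []   # 1-based inclusive, with margins
    margin = 30

    dele = ancestor.deletion_interval
    if spec.large_deletion_branch is not None:
        footprints.append((dele.start - margin, dele.end + len(
            spec.large_deletion_repeat) + margin))
        log.events.append(SimEvent(
            "large_deletion", spec.large_deletion_branch,
            dele.start, dele.end, dele.length,
            seq=anc_seq[dele.start - 1: dele.end],
            repeat=spec.large_deletion_repeat))

    def clear(a: int, b: int) -> bool:
        return all(b < fa or a > fb for fa, fb in footprints)

    # indels -----------------------------------------------------------------
    p_geom = min(1.0, 1.0 / spec.indel_mean)
    for node in branch_nodes:
        bid = tree.branch_id(node)
        if bid not in ingroup_ids:
            continue
        n_indel = rng.poisson(L * spec.indel_rate * node.length)
        made = 0
        attempts = 0
        while made < n_indel and attempts < 10_000:
            attempts += 1
            size = int(rng.geometric(p_geom))
            pos = int(rng.integers(101, L - 100 - size))   # 1-based
            if rng.random() < 0.5:
                a, b = pos, pos + size - 1                 # deleted bases, 1-based
                if not clear(a - margin, b + margin):
                    continue
                footprints.append((a - margin, b + margin))
                log.events.append(SimEvent(
                    "deletion", bid, a, b, size,
                    seq=anc_seq[a - 1: b]))
            else:
                # insertion after 1-based position pos
                if not clear(pos - margin, pos + 1 + margin):
                    continue
                ins = _random_seq(rng, size, spec.gc)
                footprints.append((pos - margin, pos + 1 + margin))
                log.events.append(SimEvent(
                    "insertion", bid, pos, pos, size, seq=ins))
            made += 1

    # substitutions ------------------------------------------------------------
    blocked = np.zeros(L, dtype=bool)
    blocked[:20] = blocked[-20:] = True
    for fa, fb in footprints:           # 1-based inclusive -> 0-based slice
        blocked[max(0, fa - 1): min(L, fb)] = True
    free = np.nonzero(~blocked)[0]
    n_subs = [int(rng.poisson(L * spec.sub_rate * n.length)) for n in branch_nodes]
    total = sum(n_subs)
    if total > len(free):
        raise SimulationError("substitution rate too high for unique placement")
    positions = rng.choice(free, size=total, replace=False)
    k = 0
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for node, n_sub in zip(branch_nodes, n_subs):
        bid = tree.branch_id(node)
        for _ in range(n_sub):
            pos = int(positions[k]); k += 1
            old = anc_seq[pos]
            new = others[old][int(rng.integers(3))]
            log.events.append(SimEvent(
                "substitution", bid, pos + 1, pos + 1, 1, seq=f"{old}>{new}"))

    leaves_out = replay_event_log(ancestor.genome, tree, log)
    return leaves_out, log, tree


# ---------------------------------------------------------------------------
# coverage simulation


@dataclass
class PromoterProgram:
    site: PromoterSite
    strength: dict[str, float]             # sample -> expected depth at the TSS


@dataclass
class CoverageSpec:
    """Parameters of the strand-specific coverage simulator."""

    promoters: list[PromoterProgram]
    terminators: list[tuple[int, str, float]]   # (position, strand, read-through)
    srna_interval: Optional[Interval] = None
    srna_multiplier: float = 30.0
    srna_ramp: int = 30                    # 5' under-representation length (bp)
    samples: tuple[str, ...] = ("lysogen", "15min", "30min", "60min", "150min")
    noise: str = "nb"                      # "nb" | "poisson" | "none"
    dispersion: float = 0.1
    library_size: int = 1_000_000
    seed: int = 0

    @classmethod
    def default_for(cls, layout: AncestorLayout) -> "CoverageSpec":
        """The study program: early leftwards arm, late rightwards arm, a
        lysogen-specific repressor unit, and the dominant stable sRNA."""
        p_left, p_right, p_rep = layout.promoters
        return cls(
            promoters=[
                PromoterProgram(p_left, {"lysogen": 5, "15min": 300, "30min": 250,
                                         "60min": 120, "150min": 40}),
                PromoterProgram(p_right, {"lysogen": 1, "15min": 5, "30min": 20,
                                          "60min": 80, "150min": 300}),
                PromoterProgram(p_rep, {"lysogen": 80}),
            ],
            terminators=list(layout.terminators),
            srna_interval=layout.srna_interval,
            srna_ramp=layout.srna_ramp,
        )


def expected_depth(genome_length: int, spec: CoverageSpec, sample: str,
                   strand: str) -> np.ndarray:
    """Noise-free expected per-base depth for one sample and strand."""
    depth = np.zeros(genome_length)
    for prog in spec.promoters:
        if prog.site.strand != strand:
            continue
        sigma = prog.strength.get(sample, 0.0)
        if sigma <= 0:
            continue
        tss0 = prog.site.tss - 1
        unit = np.zeros(genome_length)
        # the first srna_ramp bases downstream of the TSS are under-represented
        # (library protocols lose the extreme 5' end of the transcript)
        if strand == "+":
            unit[tss0:] = sigma
            for pos, tstrand, rt in spec.terminators:
                if tstrand == "+" and pos - 1 > tss0:
                    unit[pos - 1:] *= rt
            unit[tss0: tss0 + spec.srna_ramp] = 0.0
        else:
            unit[: tss0 + 1] = sigma
            for pos, tstrand, rt in spec.terminators:
                if tstrand == "-" and pos - 1 < tss0:
                    unit[: pos] *= rt
            unit[max(0, tss0 - spec.srna_ramp + 1): tss0 + 1] = 0.0
        depth += unit
    if spec.srna_interval is not None and strand == (spec.srna_interval.strand or "-"):
        iv = spec.srna_interval
        depth[iv.start - 1: iv.end] *= spec.srna_multiplier
    return depth


def simulate_coverage(genome: GenomeRecord, spec: CoverageSpec,
                      rng: Optional[np.random.Generator] = None,
                      ) -> list[CoverageTrack]:
    """Per-sample, per-strand coverage tracks, deterministic under the seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    tracks: list[CoverageTrack] = []
    for sample in spec.samples:
        for strand in "+-":
            mu = expected_depth(len(genome), spec, sample, strand)
            if spec.noise == "none":
                depth = mu
            elif spec.noise == "poisson":
                depth = rng.poisson(mu).astype(float)
            elif spec.noise == "nb":
                n = 1.0 / spec.dispersion
                depth = np.where(
                    mu > 0,
                    rng.negative_binomial(n, np.where(mu > 0, n / (n + mu), 1.0)),
                    0.0).astype(float)
            else:
                raise SimulationError(f"unknown noise model {spec.noise!r}")
            tracks.append(CoverageTrack(genome.id, sample, strand, depth,
                                        spec.library_size))
    return tracks


# ---------------------------------------------------------------------------
# one-call demo dataset and disk emission


def simulate_clade(spec: Optional[EvolutionSpec] = None,
                   seed: Optional[int] = None):
    """Generate the default study-scale dataset: (layout, leaves, log, tree)."""
    if spec is None:
        spec = EvolutionSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    layout = make_ancestor(spec, rng)
    leaves, log, tree = evolve_along_tree(layout, spec, rng)
    return layout, leaves, log, tree


def emit_dataset(outdir: str | Path, spec: Optional[EvolutionSpec] = None,
                 coverage: bool = True, seed: Optional[int] = None) -> Path:
    """Write FASTA leaves, ancestor BED, true tree, the event log and coverage
    bedGraphs under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout, leaves, log, tree = simulate_clade(spec, seed=seed)
    write_fasta([layout.genome], outdir / "ancestor.fasta")
    write_fasta(leaves.values(), outdir / "leaves.fasta")
    write_bed_features(layout.features, layout.genome.id, outdir / "genes.bed")
    tree.write_newick(outdir / "true_tree.nwk")
    log.write(outdir / "events.tsv")
    if coverage:
        cspec = CoverageSpec.default_for(layout)
        if seed is not None:
            cspec.seed = seed
        for t in simulate_coverage(layout.genome, cspec):
            name = f"coverage.{t.sample}.{'plus' if t.strand == '+' else 'minus'}.bedgraph"
            write_bedgraph(t.depth, layout.genome.id, outdir / name)
    return outdir
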