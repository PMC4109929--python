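"""Synthetic genome-pair generator with ground truth.

Produces pairs (or sets) of closely related bacterial genomes: an ancestor
of random single-copy genes is diverged per descendant by amino-acid level
substitution and back-translated with codon choice calibrated to the host
GC target, so that amino-acid identity truth is exact while the nucleotide
composition signal stays clean. Islands of novel genes with shifted GC are
planted at tRNA-adjacent positions, optionally with a recombinase-annotated
gene; gene-run deletions and family duplications add background noise.
Everything is recorded in a :class:`SimTruth` for recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .genome_io import GeneFeature, GenomeRecord, assign_ranks

AA20 = "ACDEFGHIKLMNPQRSTVWY"

RECOMBINASE_PRODUCT = "tyrosine-type site-specific recombinase"


class SimulationError(ValueError):
    pass


@dataclasses.dataclass
class IslandSpec:
    n_genes: int
    delta_gc: float
    with_trna_flank: bool = True
    with_recombinase: bool = True
    descendant: str = "a"  # 'a' or 'b'
    site: Optional[int] = None  # ancestor tRNA index; shared site => hot spot


@dataclasses.dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 600
    gene_len_mean_aa: int = 300
    gene_len_min_aa: int = 50
    host_gc: float = 0.50
    divergence: float = 0.05  # per-residue substitution probability per branch
    islands: list[IslandSpec] = dataclasses.field(default_factory=list)
    hotspot_pairs: int = 0  # shared sites carrying distinct cassettes in a and b
    loss_events: int = 0
    loss_run_max: int = 2
    family_duplications: int = 0
    trna_every: int = 50
    spacer_range: tuple[int, int] = (50, 300)
    rrna_divergence: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise SimulationError("divergence must be in [0, 1]")
        if not 0.30 <= self.host_gc <= 0.75:
            raise SimulationError("host_gc outside the reachable range [0.30, 0.75]")
        for isl in self.islands:
            if isl.n_genes < 1:
                raise SimulationError("island sizes must be >= 1")


def paper_scale_config(seed: int = 0) -> SimulationConfig:
    """A configuration at the scale of real ~2.5-3 Mb genomes (slow; not
    used in the default test run)."""
    return SimulationConfig(seed=seed, n_genes=2600, gene_len_mean_aa=300, trna_every=60)


# ---------------------------------------------------------------------------
# codon machinery

_table = CodonTable.unambiguous_dna_by_id[11]
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in _table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()
_STOPS = sorted(_table.stop_codons)

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}
_MAX_CODONS = max(len(v) for v in _CODONS_BY_AA.values())
# codon GC counts and strings laid out as (20, max_codons)
_CODON_GC = np.zeros((20, _MAX_CODONS), dtype=np.float64)
_CODON_VALID = np.zeros((20, _MAX_CODONS), dtype=bool)
_CODON_STR = np.empty((20, _MAX_CODONS), dtype="U3")
for aa, codons in _CODONS_BY_AA.items():
    i = _AA_INDEX[aa]
    for k, c in enumerate(codons):
        _CODON_GC[i, k] = c.count("G") + c.count("C")
        _CODON_VALID[i, k] = True
        _CODON_STR[i, k] = c


def _codon_probs(beta: float) -> np.ndarray:
    w = np.where(_CODON_VALID, np.exp(beta * _CODON_GC), 0.0)
    return w / w.sum(axis=1, keepdims=True)


def _expected_gc(beta: float, aa_counts: np.ndarray) -> float:
    p = _codon_probs(beta)
    per_aa = (p * _CODON_GC).sum(axis=1) / 3.0
    return float((aa_counts * per_aa).sum() / aa_counts.sum())


def _calibrate_beta(target_gc: float, aa_counts: np.ndarray) -> float:
    """Bisection on the exponential codon-bias parameter so that the
    expected coding GC equals the target for this residue composition."""
    lo, hi = -12.0, 12.0
    # short or biased proteins cannot reach every GC; clamp to the reachable
    # range for this composition (config-level validation guards the genome-
    # wide target)
    gmin, gmax = _expected_gc(lo, aa_counts), _expected_gc(hi, aa_counts)
    target_gc = min(max(target_gc, gmin + 1e-9), gmax - 1e-9)
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if _expected_gc(mid, aa_counts) < target_gc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def back_translate(protein: str, target_gc: float, rng: np.random.Generator) -> str:
    """Codon-sample a nucleotide CDS for ``protein`` with expected GC equal
    to ``target_gc``; appends a stop codon."""
    codes = np.array([_AA_INDEX[a] for a in protein], dtype=np.int64)
    counts = np.bincount(codes, minlength=20).astype(float)
    beta = _calibrate_beta(target_gc, counts)
    probs = _codon_probs(beta)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(codes))
    choice = (u[:, None] > cum[codes]).sum(axis=1)
    codons = _CODON_STR[codes, choice]
    stop_w = np.array([np.exp(beta * (c.count("G") + c.count("C"))) for c in _STOPS])
    stop = rng.choice(_STOPS, p=stop_w / stop_w.sum())
    return "".join(codons) + stop


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=length, p=p))


def random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(rng.choice(list(AA20), size=length - 1))
    return "M" + body


def mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Independent per-residue substitution to a uniformly chosen *different*
    residue with probability ``divergence``; the initial M is kept."""
    if divergence == 0.0:
        return protein
    arr = np.array(list(protein))
    hit = rng.random(len(arr)) < divergence
    hit[0] = False
    idx = np.where(hit)[0]
    for i in idx:
        choices = [a for a in AA20 if a != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def mutate_dna(seq: str, divergence: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < divergence
    for i in np.where(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# ancestor model: an ordered list of elements

@dataclasses.dataclass
class _Gene:
    family: int  # ancestor family id; island genes get fresh ids
    protein: str
    product: str = "hypothetical protein"
    island_id: Optional[int] = None
    gc_target: Optional[float] = None  # None => host GC


@dataclasses.dataclass
class _TRNA:
    index: int  # ancestor tRNA index (island insertion site id)


@dataclasses.dataclass
class _RRNA:
    seq: str


@dataclasses.dataclass
class Ancestor:
    config: SimulationConfig
    elements: list  # _Gene / _TRNA / _RRNA in genome order
    n_families: int
    trna_sites: list[int]


_TRNA_AA = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]


def _gene_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    spread = max(cfg.gene_len_mean_aa - cfg.gene_len_min_aa, 1)
    return cfg.gene_len_min_aa + int(rng.geometric(1.0 / spread))


def simulate_ancestor(config: SimulationConfig) -> Ancestor:
    """Random single-copy ancestor: ``n_genes`` CDS, tRNAs every
    ``trna_every`` genes, one 16S rRNA feature near the origin."""
    rng = np.random.default_rng([config.seed, 0])
    elements: list = [_RRNA(random_dna(1500, config.host_gc, rng))]
    trna_sites = []
    trna_idx = 0
    for fam in range(config.n_genes):
        if fam % config.trna_every == config.trna_every // 2:
            elements.append(_TRNA(trna_idx))
            trna_sites.append(trna_idx)
            trna_idx += 1
        elements.append(_Gene(fam, random_protein(_gene_length(config, rng), rng)))
    return Ancestor(config, elements, config.n_genes, trna_sites)


# ---------------------------------------------------------------------------
# descendants

@dataclasses.dataclass
class TrueIsland:
    genome_id: str
    island_id: int
    site: int  # ancestor tRNA index (-1 when not tRNA-adjacent)
    gene_loci: list[str]
    start: int
    end: int
    contig_id: str
    delta_gc: float
    with_trna_flank: bool
    with_recombinase: bool


@dataclasses.dataclass
class SimTruth:
    genome_a: str
    genome_b: str
    islands: list[TrueIsland]
    deleted_families: dict[str, list[int]]
    duplicated_families: dict[str, list[int]]
    family_of_locus: dict[str, dict[str, int]]  # genome_id -> locus -> family
    pair_identity: dict[int, float]  # family -> realized aa identity (0..1)
    expected_aai: float  # 100 * mean pair identity over surviving 1:1 families
    realized_substitution: float  # d_effective = 1 - mean identity

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _plan_islands(config: SimulationConfig, ancestor: Ancestor, rng) -> list[IslandSpec]:
    specs = [dataclasses.replace(s) for s in config.islands]
    for _ in range(config.hotspot_pairs):
        n = int(rng.integers(4, 9))
        dgc = float(rng.choice([-0.08, 0.08]))
        specs.append(IslandSpec(n, dgc, True, True, "a"))
        specs.append(IslandSpec(n + 1, -dgc, True, True, "b"))
        specs[-2].site = specs[-1].site = -2  # sentinel: assign shared below
    free = [s for s in ancestor.trna_sites]
    rng.shuffle(free)
    free = list(free)
    shared_pending: dict[int, int] = {}
    for i, s in enumerate(specs):
        if s.site == -2:
            key = i if s.descendant == "a" else i - 1
            if key in shared_pending:
                s.site = shared_pending[key]
            else:
                if not free:
                    raise SimulationError(
                        "ran out of tRNA integration sites; lower trna_every or "
                        "reduce islands"
                    )
                s.site = free.pop()
                shared_pending[i] = s.site
        elif s.site is None and s.with_trna_flank:
            if not free:
                raise SimulationError(
                    "ran out of tRNA integration sites; lower trna_every or "
                    "reduce islands"
                )
            s.site = free.pop()
        elif s.site is None:
            s.site = -1  # placed between ordinary genes
    return specs


def _make_island_genes(
    spec: IslandSpec, island_id: int, cfg: SimulationConfig, rng, next_family: list[int]
) -> list[_Gene]:
    genes = []
    recomb_at = int(rng.integers(spec.n_genes)) if spec.with_recombinase else -1
    for g in range(spec.n_genes):
        prot = random_protein(_gene_length(cfg, rng), rng)
        product = RECOMBINASE_PRODUCT if g == recomb_at else "hypothetical protein"
        genes.append(
            _Gene(
                family=next_family[0],
                protein=prot,
                product=product,
                island_id=island_id,
                gc_target=min(max(cfg.host_gc + spec.delta_gc, 0.30), 0.75),
            )
        )
        next_family[0] += 1
    return genes


def _layout(
    genome_id: str,
    elements: list,
    cfg: SimulationConfig,
    rng,
) -> tuple[GenomeRecord, dict[str, int], list[tuple[Optional[int], str, int, int]]]:
    """Concatenate elements into one contig; returns the genome, the
    locus->family map, and per-gene (island_id, locus, start, end) spans."""
    parts: list[str] = []
    feats: list[GeneFeature] = []
    fam_of: dict[str, int] = {}
    gene_spans: list[tuple[Optional[int], str, int, int]] = []
    pos = 0
    idx = 0
    lo, hi = cfg.spacer_range
    contig = f"{genome_id}_c1"
    for el in elements:
        spacer_gc = cfg.host_gc
        if isinstance(el, _Gene) and el.gc_target is not None:
            spacer_gc = el.gc_target
        spacer = random_dna(int(rng.integers(lo, hi + 1)), spacer_gc, rng)
        parts.append(spacer)
        pos += len(spacer)
        idx += 1
        if isinstance(el, _Gene):
            nt = back_translate(el.protein, el.gc_target or cfg.host_gc, rng)
            strand = "+" if rng.random() < 0.8 else "-"
            if strand == "-":
                comp = str.maketrans("ACGT", "TGCA")
                nt = nt.translate(comp)[::-1]
            tag = f"{genome_id}_{idx:05d}"
            feats.append(
                GeneFeature(tag, contig, pos, pos + len(nt), strand, "CDS",
                            product=el.product, protein=el.protein)
            )
            fam_of[tag] = el.family
            gene_spans.append((el.island_id, tag, pos, pos + len(nt)))
            parts.append(nt)
            pos += len(nt)
        elif isinstance(el, _TRNA):
            nt = random_dna(76, cfg.host_gc, rng)
            aa = _TRNA_AA[el.index % len(_TRNA_AA)]
            tag = f"{genome_id}_{idx:05d}"
            feats.append(GeneFeature(tag, contig, pos, pos + 76, "+", "tRNA",
                                     product=f"tRNA-{aa}"))
            parts.append(nt)
            pos += 76
        elif isinstance(el, _RRNA):
            tag = f"{genome_id}_{idx:05d}"
            feats.append(GeneFeature(tag, contig, pos, pos + len(el.seq), "+", "rRNA",
                                     product="16S ribosomal RNA"))
            parts.append(el.seq)
            pos += len(el.seq)
    tail = random_dna(int(rng.integers(lo, hi + 1)), cfg.host_gc, rng)
    parts.append(tail)
    genome = GenomeRecord(genome_id, [(contig, "".join(parts))], feats)
    assign_ranks(genome)
    return genome, fam_of, gene_spans


def _evolve_one(
    genome_id: str,
    ancestor: Ancestor,
    cfg: SimulationConfig,
    specs: list[IslandSpec],
    rng,
    next_family: list[int],
):
    """Mutated, island-carrying, loss-bearing copy of the ancestor."""
    elements: list = []
    mutated: dict[int, str] = {}
    for el in ancestor.elements:
        if isinstance(el, _Gene):
            prot = mutate_protein(el.protein, cfg.divergence, rng)
            mutated[el.family] = prot
            elements.append(dataclasses.replace(el, protein=prot))
        elif isinstance(el, _RRNA):
            elements.append(_RRNA(mutate_dna(el.seq, cfg.rrna_divergence, rng)))
        else:
            elements.append(el)

    # deletions: runs of 1..loss_run_max consecutive ancestor genes
    deleted: list[int] = []
    gene_positions = [i for i, el in enumerate(elements) if isinstance(el, _Gene)]
    for _ in range(cfg.loss_events):
        run = int(rng.integers(1, cfg.loss_run_max + 1))
        start = int(rng.integers(0, max(len(gene_positions) - run, 1)))
        victims = gene_positions[start:start + run]
        for p in victims:
            if isinstance(elements[p], _Gene):
                deleted.append(elements[p].family)
                elements[p] = None
    elements = [e for e in elements if e is not None]

    # duplications: re-insert a copy of an existing family elsewhere
    # (distinct source families, so each duplication marks one family)
    duplicated: list[int] = []
    for _ in range(cfg.family_duplications):
        gene_positions = [i for i, el in enumerate(elements) if isinstance(el, _Gene)]
        candidates = [p for p in gene_positions
                      if elements[p].family not in duplicated]
        src = elements[candidates[int(rng.integers(len(candidates)))]]
        dst = int(rng.integers(len(elements) + 1))
        elements.insert(dst, dataclasses.replace(src))
        duplicated.append(src.family)

    # island insertions
    my_specs = [(i, s) for i, s in enumerate(specs) if s.descendant == ("a" if genome_id.endswith("_a") else "b")]
    island_members: dict[int, list[_Gene]] = {}
    for island_id, spec in my_specs:
        genes = _make_island_genes(spec, island_id, cfg, rng, next_family)
        island_members[island_id] = genes
        if spec.site >= 0:
            at = None
            for i, el in enumerate(elements):
                if isinstance(el, _TRNA) and el.index == spec.site:
                    at = i + 1
                    break
            if at is None:
                raise SimulationError(f"tRNA site {spec.site} missing from descendant")
        else:
            at = int(rng.integers(1, len(elements)))
        elements[at:at] = genes
    return elements, mutated, deleted, duplicated, island_members


def evolve_pair(
    ancestor: Ancestor, config: SimulationConfig | None = None
) -> tuple[GenomeRecord, GenomeRecord, SimTruth]:
    """Two descendants of ``ancestor`` plus the ground-truth record."""
    cfg = config or ancestor.config
    rng_plan = np.random.default_rng([cfg.seed, 1])
    specs = _plan_islands(cfg, ancestor, rng_plan)
    next_family = [10_000_000]
    out = {}
    for which, stream in (("a", 2), ("b", 3)):
        gid = f"sim{cfg.seed}_{which}"
        rng = np.random.default_rng([cfg.seed, stream])
        elements, mutated, deleted, duplicated, island_members = _evolve_one(
            gid, ancestor, cfg, specs, rng, next_family
        )
        genome, fam_of, gene_spans = _layout(gid, elements, cfg, rng)
        out[which] = (gid, genome, mutated, deleted, duplicated, island_members,
                      fam_of, gene_spans)

    gid_a, genome_a = out["a"][0], out["a"][1]
    gid_b, genome_b = out["b"][0], out["b"][1]

    # realized per-family identity between the two descendants
    surviving = {}
    del_a, del_b = set(out["a"][3]), set(out["b"][3])
    for fam in range(ancestor.n_families):
        if fam in del_a or fam in del_b:
            continue
        pa, pb = out["a"][2][fam], out["b"][2][fam]
        same = sum(1 for x, y in zip(pa, pb) if x == y)
        surviving[fam] = same / len(pa)
    mean_ident = float(np.mean(list(surviving.values()))) if surviving else 0.0

    islands: list[TrueIsland] = []
    for which in ("a", "b"):
        gid, genome = out[which][0], out[which][1]
        island_members = out[which][5]
        gene_spans = out[which][7]
        for island_id, genes in island_members.items():
            spec = specs[island_id]
            spans = [(tag, s, e) for iid, tag, s, e in gene_spans if iid == island_id]
            islands.append(
                TrueIsland(
                    genome_id=gid,
                    island_id=island_id,
                    site=spec.site,
                    gene_loci=[t for t, _, _ in spans],
                    start=min(s for _, s, _ in spans),
                    end=max(e for _, _, e in spans),
                    contig_id=genome.contigs[0][0],
                    delta_gc=spec.delta_gc,
                    with_trna_flank=spec.with_trna_flank,
                    with_recombinase=spec.with_recombinase,
                )
            )

    truth = SimTruth(
        genome_a=gid_a,
        genome_b=gid_b,
        islands=islands,
        deleted_families={gid_a: out["a"][3], gid_b: out["b"][3]},
        duplicated_families={gid_a: out["a"][4], gid_b: out["b"][4]},
        family_of_locus={gid_a: out["a"][6], gid_b: out["b"][6]},
        pair_identity=surviving,
        expected_aai=100.0 * mean_ident,
        realized_substitution=1.0 - mean_ident,
    )
    return genome_a, genome_b, truth


def evolve_set(ancestor: Ancestor, n: int, config: SimulationConfig | None = None):
    """``n`` independent descendants (no islands) with per-genome family
    maps; used for ortholog-group and tree tests. Family duplications are
    planted in the first descendant only, so ``family_duplications`` counts
    multi-copy families across the whole set."""
    cfg = config or ancestor.config
    genomes = []
    family_maps = {}
    next_family = [10_000_000]
    for d in range(n):
        gid = f"sim{cfg.seed}_d{d}_a"  # _a suffix so _evolve_one matches 'a' specs
        rng = np.random.default_rng([cfg.seed, 10 + d])
        dcfg = cfg if d == 0 else dataclasses.replace(cfg, family_duplications=0)
        elements, _mut, _del, _dup, _isl = _evolve_one(
            gid, ancestor, dcfg, [], rng, next_family
        )
        genome, fam_of, _ = _layout(gid, elements, cfg, rng)
        genomes.append(genome)
        family_maps[gid] = fam_of
    return genomes, family_maps


@dataclasses.dataclass
class RecoveryResult:
    precision: float
    recall: float
    n_called: int
    n_true: int
    precision_defined: bool = True


def evaluate_recovery(
    called_islands, truth: SimTruth, genomes: dict[str, GenomeRecord],
    gene_tolerance: int = 2,
) -> RecoveryResult:
    """Match called islands against planted truth.

    A call matches a true island when their gene sets overlap by >= 50% of
    the larger set and both boundaries are within ``gene_tolerance`` genes.
    With no calls, precision is undefined and reported as 1.0 with
    ``precision_defined=False``.
    """
    cds_order = {
        gid: [f.locus_tag for f in g.features if f.ftype == "CDS"]
        for gid, g in genomes.items()
    }
    pos = {gid: {t: i for i, t in enumerate(order)} for gid, order in cds_order.items()}

    def bounds(gid, loci):
        idxs = [pos[gid][t] for t in loci if t in pos[gid]]
        return (min(idxs), max(idxs)) if idxs else (None, None)

    true_by_genome: dict[str, list[TrueIsland]] = {}
    for t in truth.islands:
        true_by_genome.setdefault(t.genome_id, []).append(t)

    matched_true: set[tuple[str, int]] = set()
    n_matched_calls = 0
    for isl in called_islands:
        gid = isl.genome_id
        cset = set(isl.gene_loci)
        clo, chi = bounds(gid, isl.gene_loci)
        hit = False
        for t in true_by_genome.get(gid, []):
            tset = set(t.gene_loci)
            ov = len(cset & tset) / max(len(cset), len(tset))
            tlo, thi = bounds(gid, t.gene_loci)
            if (
                ov >= 0.5
                and clo is not None
                and tlo is not None
                and abs(clo - tlo) <= gene_tolerance
                and abs(chi - thi) <= gene_tolerance
            ):
                matched_true.add((gid, t.island_id))
                hit = True
        if hit:
            n_matched_calls += 1

    n_called = len(called_islands)
    n_true = len(truth.islands)
    if n_called == 0:
        precision, defined = 1.0, False
    else:
        precision, defined = n_matched_calls / n_called, True
    recall = len(matched_true) / n_true if n_true else 1.0
    return RecoveryResult(precision, recall, n_called, n_true, defined)
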