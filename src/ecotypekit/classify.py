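"""Metabolic-module inventory from product annotations plus optional
homology evidence, and taxonomic-rank calls from AAI x 16S identity zones.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import yaml

from .genome_io import GenomeRecord, Proteome
from .homology import local_align


class ClassifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# module inventory

@dataclasses.dataclass
class ModuleDefinition:
    module_id: str
    gene_symbols: list[str]
    keywords: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    reference_proteins: dict[str, str] = dataclasses.field(default_factory=dict)
    min_fraction_present: float = 1.0
    max_gene_gap: int = 5
    note: str = ""

    def __post_init__(self) -> None:
        if not self.gene_symbols and not self.keywords:
            raise ClassifyError(f"module {self.module_id}: no symbols and no keywords")
        for sym in self.gene_symbols:
            self.keywords.setdefault(sym, [sym.lower()])

    @property
    def single_gene(self) -> bool:
        return len(self.gene_symbols) == 1


def load_module_definitions(path=None) -> list[ModuleDefinition]:
    """Load module definitions from YAML (default: the bundled set covering
    methylotrophy and nitrogen-metabolism modules)."""
    if path is None:
        text = resources.files("ecotypekit.data").joinpath("modules.yaml").read_text()
    else:
        text = open(path).read()
    raw = yaml.safe_load(text)
    defs = []
    for entry in raw["modules"]:
        defs.append(
            ModuleDefinition(
                module_id=entry["module_id"],
                gene_symbols=list(entry.get("gene_symbols", [])),
                keywords={k: [s.lower() for s in v] for k, v in entry.get("keywords", {}).items()},
                reference_proteins=entry.get("reference_proteins", {}),
                min_fraction_present=float(entry.get("min_fraction_present", 1.0)),
                max_gene_gap=int(entry.get("max_gene_gap", 5)),
                note=entry.get("note", ""),
            )
        )
    return defs


def _matches(
    feature,
    protein: str | None,
    module: ModuleDefinition,
    min_identity: float,
    min_cov: float,
) -> list[str]:
    """Symbols of ``module`` that this gene matches (keyword or homology)."""
    hits = []
    product = feature.product.lower()
    for sym in module.gene_symbols:
        if any(kw in product for kw in module.keywords.get(sym, [])):
            hits.append(sym)
            continue
        ref = module.reference_proteins.get(sym)
        if ref and protein:
            r = local_align(protein, ref)
            if r.pct_identity >= min_identity and min(r.qcov, r.scov) >= min_cov:
                hits.append(sym)
    return hits


def inventory_modules(
    genome: GenomeRecord,
    proteome: Proteome | None,
    module_defs: list[ModuleDefinition],
    min_identity: float = 30.0,
    min_cov: float = 0.70,
) -> dict[str, int]:
    """Copy number per module for one genome.

    Multi-symbol modules count gene clusters: matched genes are grouped into
    runs whose consecutive members are within ``max_gene_gap`` gene ranks,
    and a run counts when it covers >= min_fraction_present of the symbols.
    Single-symbol modules report plain matching-gene counts.
    """
    prot_of = proteome.as_dict() if proteome else {}
    cds = [f for f in genome.features if f.ftype == "CDS"]
    out: dict[str, int] = {}
    for module in module_defs:
        matched: list[tuple[int, set[str]]] = []  # (gene index, matched symbols)
        for i, f in enumerate(cds):
            syms = _matches(f, prot_of.get(f.locus_tag, f.protein), module,
                            min_identity, min_cov)
            if syms:
                matched.append((i, set(syms)))
        if module.single_gene:
            out[module.module_id] = len(matched)
            continue
        count = 0
        cluster: set[str] = set()
        last = None
        need = module.min_fraction_present * len(module.gene_symbols)
        for i, syms in matched:
            if last is not None and i - last > module.max_gene_gap:
                if len(cluster) >= need:
                    count += 1
                cluster = set()
            cluster |= syms
            last = i
        if cluster and len(cluster) >= need:
            count += 1
        out[module.module_id] = count
    return out


def inventory_matrix(
    genomes: list[GenomeRecord],
    proteomes: dict[str, Proteome] | None = None,
    module_defs: list[ModuleDefinition] | None = None,
):
    """Modules x genomes copy-number matrix (pandas DataFrame)."""
    import pandas as pd

    defs = module_defs or load_module_definitions()
    cols = {}
    for g in genomes:
        prot = (proteomes or {}).get(g.genome_id)
        cols[g.genome_id] = inventory_modules(g, prot, defs)
    return pd.DataFrame(cols, index=[m.module_id for m in defs]).fillna(0).astype(int)


# ---------------------------------------------------------------------------
# taxonomic-rank zoning

@dataclasses.dataclass
class RankThresholds:
    species_aai_min: float = 86.0
    genus_zone: tuple[float, float] = (62.9, 67.3)  # different named genera
    ambiguous_zone: tuple[float, float] = (69.0, 74.3)  # genus and species mixed
    species_16s_min: float = 99.0
    novel_16s_max: float = 97.0

    def __post_init__(self) -> None:
        g0, g1 = self.genus_zone
        a0, a1 = self.ambiguous_zone
        if not (g0 < g1 <= a0 < a1 <= self.species_aai_min):
            raise ClassifyError("rank zones must be ordered and non-overlapping")


CALLS = ("same_species", "genus_or_species_ambiguous", "different_genus", "beyond_genus")


@dataclasses.dataclass
class RankCall:
    genome_a: str
    genome_b: str
    aai: float
    rrna_id: float | None
    call: str
    low_confidence: bool = False
    consistency_flag: bool = False


def classify_pair(
    aai_result,
    rrna_id: float | None = None,
    thresholds: RankThresholds | None = None,
) -> RankCall:
    """Rank call from AAI (and, when available, 16S identity).

    Zones follow the empirical AAI bands: >= species_aai_min same species;
    ambiguous_zone mixes genus and species rank; genus_zone separates named
    genera; below it lies beyond-genus divergence. AAI values falling in the
    gaps between zones get the nearest zone's call flagged low-confidence.
    A consistency flag marks 16S/AAI disagreement about species rank.
    """
    th = thresholds or RankThresholds()
    if hasattr(aai_result, "aai"):
        aai = aai_result.aai
        ga, gb = aai_result.genome_a, aai_result.genome_b
    else:
        aai = float(aai_result)
        ga = gb = ""
    if aai is None or aai != aai:
        raise ClassifyError("AAI undefined: cannot classify")
    g0, g1 = th.genus_zone
    a0, a1 = th.ambiguous_zone
    low = False
    if aai >= th.species_aai_min:
        call = "same_species"
    elif a0 <= aai <= a1:
        call = "genus_or_species_ambiguous"
    elif g0 <= aai <= g1:
        call = "different_genus"
    elif aai < g0:
        call = "beyond_genus"
    elif g1 < aai < a0:
        low = True
        call = "different_genus" if aai - g1 <= a0 - aai else "genus_or_species_ambiguous"
    else:  # a1 < aai < species_aai_min
        low = True
        call = (
            "genus_or_species_ambiguous"
            if aai - a1 <= th.species_aai_min - aai
            else "same_species"
        )
    flag = False
    if rrna_id is not None:
        species_by_16s = rrna_id >= th.species_16s_min
        species_by_aai = aai >= th.species_aai_min
        flag = species_by_16s != species_by_aai
    return RankCall(ga, gb, aai, rrna_id, call, low, flag)


def write_rank_calls_tsv(calls: list[RankCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_a\tgenome_b\taai\trrna_id\tcall\tlow_confidence\tconsistency_flag\n")
        for c in calls:
            r = f"{c.rrna_id:.2f}" if c.rrna_id is not None else "."
            fh.write(
                f"{c.genome_a}\t{c.genome_b}\t{c.aai:.2f}\t{r}\t{c.call}\t"
                f"{int(c.low_confidence)}\t{int(c.consistency_flag)}\n"
            )
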