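"""End-to-end orchestration of the comparative-genomics stages."""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from pathlib import Path

import yaml

from . import classify, genome_io, homology, islands, phylogenomics

log = logging.getLogger("ecotypekit")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


@dataclasses.dataclass
class GenomeInput:
    genome_id: str
    fasta: str
    features: str
    dialect: str = "gff3"


@dataclasses.dataclass
class PipelineConfig:
    genomes: list[GenomeInput]
    outdir: str
    seed: int = 0
    scgo_min_identity: float = 50.0
    scgo_min_cov: float = 0.70
    aai_min_identity: float = homology.AAI_MIN_IDENTITY
    aai_min_cov: float = homology.AAI_MIN_COV
    bootstrap_reps: int = 100
    island_config: islands.IslandConfig = dataclasses.field(default_factory=islands.IslandConfig)
    module_definitions: str | None = None
    stages: tuple[str, ...] = ("aai", "rrna", "tree", "islands", "inventory", "classify")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path))
        genomes = [GenomeInput(**g) for g in raw.pop("genomes")]
        island_raw = raw.pop("island_config", {})
        if "recombinase_keywords" in island_raw:
            island_raw["recombinase_keywords"] = tuple(island_raw["recombinase_keywords"])
        island_cfg = islands.IslandConfig(**island_raw)
        stages = tuple(
            raw.pop("stages", ("aai", "rrna", "tree", "islands", "inventory", "classify"))
        )
        return cls(genomes=genomes, island_config=island_cfg, stages=stages, **raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _extract_16s(genome) -> str | None:
    for f in genome.features:
        if f.ftype == "rRNA" and "16s" in f.product.lower():
            return genome.contig_seq(f.contig_id)[f.start:f.end]
    return None


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages; returns the output directory.

    Any stage failure raises :class:`PipelineError` naming the stage; partial
    outputs are retained and MANIFEST marks per-stage completeness.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setLevel(logging.INFO)
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest: dict[str, str] = {}
    digest = config.digest()
    log.info("config digest %s seed %d", digest, config.seed)
    with open(outdir / "config.yaml", "w") as out:
        yaml.safe_dump(dataclasses.asdict(config), out, default_flow_style=False)

    def done(stage):
        manifest[stage] = "complete"
        with open(outdir / "MANIFEST.json", "w") as mf:
            json.dump({"config_digest": digest, "stages": manifest}, mf, indent=1)

    try:
        stage = "load"
        genomes = []
        for gin in config.genomes:
            genomes.append(
                genome_io.read_genome(gin.fasta, gin.features, gin.dialect, gin.genome_id)
            )
        if len(genomes) < 2:
            raise PipelineError("load", "need >= 2 genomes for comparative stages")
        proteomes = [genome_io.extract_proteome(g) for g in genomes]
        prot_of = {p.genome_id: p for p in proteomes}
        done("load")

        aai_results = {}
        if "aai" in config.stages:
            stage = "aai"
            import pandas as pd

            ids = [p.genome_id for p in proteomes]
            mat = pd.DataFrame(100.0, index=ids, columns=ids)
            for pa, pb in itertools.combinations(proteomes, 2):
                rbh = homology.reciprocal_best_hits(
                    pa, pb, config.aai_min_identity, config.aai_min_cov
                )
                homology.write_rbh_tsv(
                    rbh, outdir / f"rbh_{pa.genome_id}_{pb.genome_id}.tsv"
                )
                if rbh:
                    import numpy as np

                    idents = np.array([p.pct_identity for p in rbh])
                    res = homology.AAIResult(
                        pa.genome_id, pb.genome_id, float(idents.mean()), len(rbh),
                        float(idents.std(ddof=1)) if len(rbh) > 1 else 0.0,
                    )
                else:
                    res = None
                aai_results[(pa.genome_id, pb.genome_id)] = res
                val = res.aai if res else float("nan")
                mat.loc[pa.genome_id, pb.genome_id] = val
                mat.loc[pb.genome_id, pa.genome_id] = val
            genome_io.write_report(mat, outdir / "aai_matrix.tsv", "matrix")
            done("aai")

        rrna_ids = {}
        if "rrna" in config.stages:
            stage = "rrna"
            seqs = {g.genome_id: _extract_16s(g) for g in genomes}
            seqs = {k: v for k, v in seqs.items() if v}
            if len(seqs) >= 2:
                mat16 = homology.rrna_identity_matrix(seqs)
                genome_io.write_report(mat16, outdir / "rrna_identity_matrix.tsv", "matrix")
                for ga, gb in itertools.combinations(sorted(seqs), 2):
                    rrna_ids[(ga, gb)] = float(mat16.loc[ga, gb])
            done("rrna")

        if "tree" in config.stages and len(genomes) < 3:
            stage = "tree"
            log.warning("tree stage skipped: fewer than 3 genomes")
            manifest["tree"] = "skipped (<3 genomes)"
        elif "tree" in config.stages:
            stage = "tree"
            groups = phylogenomics.build_ortholog_groups(
                proteomes, config.scgo_min_identity, config.scgo_min_cov
            )
            phylogenomics.write_groups_tsv(groups, outdir / "ortholog_groups.tsv")
            scgo = phylogenomics.select_scgo(groups, {p.genome_id for p in proteomes})
            log.info("%d ortholog groups, %d single-copy", len(groups), len(scgo))
            genome_of_locus = {}
            msas = {}
            for g in scgo:
                seqs = {}
                for gid, loci in g.members.items():
                    tag = loci[0]
                    seqs[tag] = prot_of[gid].as_dict()[tag]
                    genome_of_locus[tag] = gid
                msas[g.group_id] = phylogenomics.align_group(seqs)
            concat = phylogenomics.concatenate(msas, genome_of_locus)
            genome_io.write_report(concat, outdir / "concatenated.phy", "alignment")
            tree = phylogenomics.bootstrap_support(
                concat, n_reps=config.bootstrap_reps, seed=config.seed
            )
            genome_io.write_report(tree, outdir / "tree.nwk", "tree")
            done("tree")

        if "islands" in config.stages:
            stage = "islands"
            for ga, gb in itertools.combinations(genomes, 2):
                rbh = homology.reciprocal_best_hits(
                    prot_of[ga.genome_id], prot_of[gb.genome_id],
                    config.scgo_min_identity, config.scgo_min_cov,
                )
                swapped = [
                    homology.RBHPair(p.locus_b, p.locus_a, p.pct_identity, p.min_cov, p.score)
                    for p in rbh
                ]
                isl_a = islands.call_islands(ga, gb, rbh, config=config.island_config)
                isl_b = islands.call_islands(gb, ga, swapped, config=config.island_config)
                tag = f"{ga.genome_id}_{gb.genome_id}"
                genome_io.write_report(isl_a, outdir / f"islands_{tag}_a.tsv", "islands")
                genome_io.write_report(isl_b, outdir / f"islands_{tag}_b.tsv", "islands")
                spots = islands.find_hotspots(isl_a, isl_b)
                islands.write_hotspots_tsv(spots, outdir / f"hotspots_{tag}.tsv")
            done("islands")

        if "inventory" in config.stages:
            stage = "inventory"
            defs = classify.load_module_definitions(config.module_definitions)
            inv = classify.inventory_matrix(genomes, prot_of, defs)
            inv.to_csv(outdir / "inventory_matrix.tsv", sep="\t", index_label="module")
            done("inventory")

        if "classify" in config.stages:
            stage = "classify"
            calls = []
            for (ga, gb), res in sorted(aai_results.items()):
                if res is None:
                    continue
                rr = rrna_ids.get((ga, gb)) or rrna_ids.get((gb, ga))
                calls.append(classify.classify_pair(res, rr))
            classify.write_rank_calls_tsv(calls, outdir / "rank_calls.tsv")
            done("classify")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage name
        raise PipelineError(stage, str(exc)) from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    return outdir
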