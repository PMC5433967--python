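"""End-to-end orchestration of the study-shaped analysis.

A single YAML config defines the dataset (per-locus FASTA paths plus a
metadata TSV, or a synthetic-generation block), the resampling effort,
and the rate priors; ``run_all`` executes ingest -> haplotype network ->
diversity table -> recombination suite -> divergence table and writes a
report bundle with a reproducibility manifest. A rerun with the same
config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import divergence as dv
from . import diversity as dvr
from . import haplotypes as hap
from . import recombination as rc
from . import seqio
from . import synthetic_data as syn

logger = logging.getLogger("clonescape")

# fixed per-stage seed offsets fanned out from the global seed
STAGE_OFFSETS = {"diversity": 1_000, "recombination": 2_000, "divergence": 3_000}


@dataclass
class RunConfig:
    label: str = "run"
    loci: list[str] = field(default_factory=list)  # FASTA paths, locus order
    metadata: str | None = None  # TSV path
    synthetic: dict | None = None  # SimulationConfig fields; alternative input
    missing_policy: str = "drop_incomplete"
    clone_correct: bool = True
    gap_mode: str = "missing"
    strip_ambiguous: bool = True
    connection_limit: int | None = None
    confidence: float = 0.95
    reps: int = 1000
    permutations: int = 999
    rates: dict[str, float] = field(
        default_factory=lambda: dict(dv.DEFAULT_RATES)
    )
    seed: int = 0
    outdir: str = "clonescape_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if self.synthetic is None:
            if not self.loci or self.metadata is None:
                raise ValueError("config needs loci + metadata, or a synthetic block")
            for p in [*self.loci, self.metadata]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file missing: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_dataset(config: RunConfig) -> seqio.MultilocusDataset:
    if config.synthetic is not None:
        sim_cfg = syn.config_from_dict(
            {"seed": config.seed, **config.synthetic}
        )
        ds, _ = syn.simulate(sim_cfg)
        return ds
    loci = [seqio.read_fasta(p) for p in config.loci]
    meta = seqio.read_metadata(config.metadata)
    return seqio.MultilocusDataset(loci, meta)


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute every analysis stage and write the report bundle.

    Returns a map of artifact name -> path. Any stage failure removes the
    partially written output directory before re-raising.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    try:
        logger.info("[ingest] loading dataset %s", config.label)
        ds = load_dataset(config)
        if config.strip_ambiguous:
            loci = []
            for aln in ds.loci:
                stripped, removed = seqio.strip_ambiguous_columns(aln)
                logger.debug(
                    "[ingest] %s: removed %d ambiguous columns",
                    aln.locus_name, len(removed),
                )
                loci.append(stripped)
            ds = seqio.MultilocusDataset(loci, ds.metadata)
        concat, offsets = seqio.concatenate(ds, config.missing_policy)

        logger.info("[haplotypes] collapsing and building network")
        haps = hap.collapse_haplotypes(concat, config.gap_mode)
        limit = hap.parsimony_connection_limit(
            len(haps), concat.length, config.confidence,
            override=config.connection_limit,
        )
        net = hap.build_parsimony_network(haps, limit, config.gap_mode)
        p = outdir / "network.gml"
        hap.write_gml(net, p, ds.metadata)
        artifacts["network_gml"] = p
        ct = hap.phenotype_crosstab(haps, ds.metadata)
        p = outdir / "crosstab.tsv"
        ct.to_csv(p, sep="\t", index=False)
        artifacts["crosstab_tsv"] = p

        logger.info("[diversity] per-population table")
        div_rows = dvr.diversity_table(
            ds, config.label, config.missing_policy,
            reps=config.reps, seed=config.seed + STAGE_OFFSETS["diversity"],
        )
        p = outdir / "diversity.tsv"
        _write_rows(p, [r.as_row() for r in div_rows])
        artifacts["diversity_tsv"] = p

        logger.info("[recombination] 4GT / Rm / index of association")
        rec_rows = rc.recombination_suite(
            ds, config.clone_correct, config.permutations,
            seed=config.seed + STAGE_OFFSETS["recombination"],
            missing_policy=config.missing_policy,
        )
        p = outdir / "recombination.tsv"
        _write_rows(p, [r.as_row() for r in rec_rows])
        artifacts["recombination_tsv"] = p

        logger.info("[divergence] pairwise D_xy / D_A / dating")
        rates = [dv.RatePrior(n, mu) for n, mu in config.rates.items()]
        divg_rows = dv.divergence_table(
            ds, rates, config.reps,
            seed=config.seed + STAGE_OFFSETS["divergence"],
            clone_correct_first=config.clone_correct,
            missing_policy=config.missing_policy,
        )
        p = outdir / "divergence.tsv"
        _write_rows(p, [r.as_row() for r in divg_rows])
        artifacts["divergence_tsv"] = p

        manifest = {
            "label": config.label,
            "seed": config.seed,
            "stage_seeds": {
                k: config.seed + v for k, v in STAGE_OFFSETS.items()
            },
            "connection_limit": limit,
            "locus_offsets": [list(o) for o in offsets],
            "inputs": {
                str(p): _sha256(Path(p))
                for p in ([*config.loci, config.metadata] if config.synthetic is None else [])
            },
            "synthetic": config.synthetic,
            "outputs": {},
        }
        for name, path in artifacts.items():
            manifest["outputs"][name] = _sha256(path)
        p = outdir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        artifacts["manifest_json"] = p
    except Exception:
        logger.error("[pipeline] stage failed; removing partial outputs")
        shutil.rmtree(outdir, ignore_errors=True)
        raise
    return artifacts


def _write_rows(path: Path, rows: list[dict]) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
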