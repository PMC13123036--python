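"""Plain-text import/export: haplotype CSV, map CSV, PED/MAP, YAML strategies.

All on-disk formats are text.  Haplotypes are written transposed (rows are
loci, columns are haplotypes named ``<animal>_1``/``<animal>_2``) which is
the layout most phasing tools emit.  The PED/MAP dialect follows the classic
6-column pedigree prefix with two allele columns per chip locus (alleles
coded 1/2); the MAP file carries the cM position in column 3 and 0 for the
absent bp coordinate.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome_sim import GeneticMap, HaplotypePanel
from .scheme import ANY, DonorSpec, LayerSpec, StrategyConfig

__all__ = [
    "write_map_csv",
    "read_map_csv",
    "write_haplotypes_csv",
    "read_haplotypes_csv",
    "write_ped_map",
    "write_metrics_csv",
    "write_metrics_json",
    "write_evaluation_csv",
    "write_contributions_csv",
    "load_strategy_yaml",
    "dump_strategy_yaml",
]


def write_map_csv(gmap: GeneticMap, path: str | Path) -> None:
    gmap.to_frame().to_csv(path, index=False)


def read_map_csv(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path)
    chrom = df["chrom"].to_numpy(np.int32)
    return GeneticMap(
        chrom=chrom,
        cm=df["cm"].to_numpy(float),
        chip_mask=df["is_chip"].to_numpy(bool),
        qtl_mask=df["is_qtl"].to_numpy(bool),
        n_chromosomes=int(chrom.max()) + 1,
        chrom_length_cm=float(np.ceil(df["cm"].max())),
    )


def write_haplotypes_csv(panel: HaplotypePanel, path: str | Path, loci: np.ndarray | None = None) -> None:
    haps = panel.haplotypes(loci=loci)  # [n, 2, L]
    cols = {}
    for k, aid in enumerate(panel.ids):
        cols[f"{aid}_1"] = haps[k, 0]
        cols[f"{aid}_2"] = haps[k, 1]
    pd.DataFrame(cols).to_csv(path, index_label="locus")


def read_haplotypes_csv(path: str | Path) -> HaplotypePanel:
    df = pd.read_csv(path, index_col="locus")
    names = [c.rsplit("_", 1) for c in df.columns]
    ids = sorted({int(n) for n, _ in names})
    n, L = len(ids), len(df)
    alleles = np.zeros((2, n, L), dtype=np.uint8)
    for k, aid in enumerate(ids):
        alleles[0, k] = df[f"{aid}_1"].to_numpy(np.uint8)
        alleles[1, k] = df[f"{aid}_2"].to_numpy(np.uint8)
    return HaplotypePanel(alleles, np.zeros_like(alleles, dtype=np.int32), np.array(ids, dtype=np.int64))


def write_ped_map(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    pedigree: pd.DataFrame,
    prefix: str | Path,
) -> None:
    """Write ``<prefix>.ped`` / ``<prefix>.map`` for the chip loci."""
    prefix = Path(prefix)
    chip = gmap.chip_idx
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j, l in enumerate(chip):
            fh.write(f"{gmap.chrom[l] + 1}\tsnp{j}\t{gmap.cm[l]:.6f}\t0\n")
    ped = pedigree.set_index("id")
    haps = panel.haplotypes(loci=chip)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for k, aid in enumerate(panel.ids):
            rec = ped.loc[int(aid)]
            lead = [1, int(aid), max(int(rec["sire"]), 0), max(int(rec["dam"]), 0), int(rec["sex"]), -9]
            geno = np.empty(2 * chip.size, dtype=np.int8)
            geno[0::2] = haps[k, 0] + 1
            geno[1::2] = haps[k, 1] + 1
            fh.write(" ".join(str(x) for x in lead) + " " + " ".join(map(str, geno)) + "\n")


def write_metrics_csv(tables: list[pd.DataFrame], out_dir: str | Path, stem: str) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rep, df in enumerate(tables):
        p = out_dir / f"{stem}_rep{rep}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


def write_metrics_json(tables: list[pd.DataFrame], path: str | Path) -> None:
    """All replicates of one scenario as a single JSON document."""
    import json

    doc = [df.to_dict(orient="records") for df in tables]
    Path(path).write_text(json.dumps(doc, indent=1, default=float))


def write_evaluation_csv(result, prefix: str | Path) -> None:
    """GEBVs (``<prefix>_gebv.csv``) and SNP effects (``<prefix>_effects.csv``)."""
    prefix = Path(prefix)
    pd.DataFrame({"animal": result.training_ids, "gebv": result.gebv}).to_csv(
        prefix.parent / f"{prefix.name}_gebv.csv", index=False
    )
    pd.DataFrame({"locus": np.arange(result.snp_effects.size), "effect": result.snp_effects}).to_csv(
        prefix.parent / f"{prefix.name}_effects.csv", index=False
    )


def write_contributions_csv(solution, path: str | Path) -> None:
    """An OCS solution as (candidate, contribution) rows plus a status header."""
    with open(path, "w") as fh:
        fh.write(f"# status={solution.status} objective={solution.objective:.6g} "
                 f"xKx={solution.xKx:.6g} bound={solution.bound:.6g}\n")
        pd.DataFrame(
            {"candidate": solution.candidate_ids, "contribution": solution.contributions}
        ).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# strategy YAML


def dump_strategy_yaml(strategy: StrategyConfig, path: str | Path) -> None:
    doc = {
        "strategy_id": strategy.strategy_id,
        "label": strategy.label,
        "n_dams_total": strategy.n_dams_total,
        "donors": [
            {"criterion": d.criterion, "n": d.n, "pool_depth": d.pool_depth} for d in strategy.donors
        ],
        "layers": [
            {"layer": l.layer, "parts": [list(p) for p in l.parts], "eligible": list(l.eligible)}
            for l in strategy.layers
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_strategy_yaml(path: str | Path) -> StrategyConfig:
    doc = yaml.safe_load(Path(path).read_text())
    donors = tuple(DonorSpec(d["criterion"], int(d["n"]), int(d.get("pool_depth", 10))) for d in doc.get("donors", []))
    layers = tuple(
        LayerSpec(
            int(l["layer"]),
            tuple((str(s), int(n)) for s, n in l["parts"]),
            tuple(l.get("eligible", ANY)),
        )
        for l in doc.get("layers", [])
    )
    return StrategyConfig(
        strategy_id=int(doc["strategy_id"]),
        label=str(doc.get("label", f"strategy {doc['strategy_id']}")),
        donors=donors,
        layers=layers,
        n_dams_total=int(doc.get("n_dams_total", 400)),
    )
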