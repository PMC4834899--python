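"""Plain-text readers and writers for the package's tabular formats.

* Pedigree: CSV with columns id, sire, dam, sex, generation (0 = unknown
  parent).
* Ordered genotypes: a pair of TSV matrices (maternal, paternal) with rows =
  individuals and columns = marker ids, entries in {0, 1} counting the A1
  allele, plus a marker-map TSV (marker, chrom, pos_morgan, role).
* QTL alleles: long-format TSV (individual, qtl, maternal_allele,
  paternal_allele).
* Phenotypes: CSV (id, y, genetic_value, env).
* Simulation config and scenario manifests: YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import OrderedGenotypes
from .imprint import ImprintScenario, PhenotypeTable
from .popsim import ExportedDataset, SimConfig

__all__ = [
    "write_pedigree", "read_pedigree",
    "write_ordered_genotypes", "read_ordered_genotypes",
    "write_dataset", "write_phenotypes", "read_phenotypes",
    "write_sim_config", "read_sim_config",
    "write_scenario", "read_scenario",
]


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ordered_genotypes(genotypes: OrderedGenotypes, prefix) -> None:
    """Write <prefix>.maternal.tsv and <prefix>.paternal.tsv matrices."""
    prefix = Path(prefix)
    for name, mat in (("maternal", genotypes.maternal),
                      ("paternal", genotypes.paternal)):
        frame = pd.DataFrame(mat, index=genotypes.ids,
                             columns=genotypes.marker_ids)
        frame.index.name = "id"
        frame.to_csv(Path(str(prefix) + f".{name}.tsv"), sep="\t")


def read_ordered_genotypes(prefix) -> OrderedGenotypes:
    prefix = Path(prefix)
    mats = {}
    for name in ("maternal", "paternal"):
        frame = pd.read_csv(Path(str(prefix) + f".{name}.tsv"), sep="\t",
                            index_col="id")
        mats[name] = frame
    m = mats["maternal"]
    return OrderedGenotypes(
        ids=m.index.to_numpy(), marker_ids=m.columns.to_numpy(),
        maternal=m.to_numpy(), paternal=mats["paternal"].to_numpy(),
    )


def write_dataset(data: ExportedDataset, out_dir) -> None:
    """Write genotypes, marker map, pedigree and QTL alleles of an export."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ordered_genotypes(data.genotypes, out / "genotypes")
    data.genome_map.to_frame().to_csv(out / "marker_map.tsv", sep="\t", index=False)
    write_pedigree(data.pedigree, out / "pedigree.csv")
    data.qtl_table().to_csv(out / "qtl_alleles.tsv", sep="\t", index=False)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.to_frame().to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sim_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def read_sim_config(path) -> SimConfig:
    with open(path) as fh:
        return SimConfig(**yaml.safe_load(fh))


def write_scenario(scenario: ImprintScenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(
            rho=float(scenario.rho), s=float(scenario.s),
            seed=int(scenario.seed),
            mi=[int(i) for i in scenario.mi],
            pi=[int(i) for i in scenario.pi],
            ni=[int(i) for i in scenario.ni],
        ), fh, sort_keys=False)


def read_scenario(path) -> ImprintScenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ImprintScenario(rho=d["rho"], s=d["s"], ni=np.array(d["ni"]),
                           mi=np.array(d["mi"]), pi=np.array(d["pi"]),
                           seed=d.get("seed", 0))
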