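"""Plain-text readers and writers for the simulated datasets."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .synthetic_data import (MISSING, GenotypeMatrix, MarkerMap,
                             PhenotypeTable, TraitArchitecture)


def write_marker_map_csv(mm: MarkerMap, path) -> None:
    mm.to_frame().to_csv(path, index=False)


def read_marker_map_csv(path) -> MarkerMap:
    df = pd.read_csv(path)
    return MarkerMap(df["marker_id"].to_numpy(dtype=object),
                     df["chromosome"].to_numpy(),
                     df["position_bp"].to_numpy(),
                     df["position_cM"].to_numpy())


def write_genotype_csv(geno: GenotypeMatrix, path) -> None:
    """Rows = RILs, columns = marker ids, missing written as NA."""
    df = pd.DataFrame(geno.dosages.astype(object), index=list(geno.ril_ids),
                      columns=list(geno.markers.marker_id))
    df = df.where(geno.dosages != MISSING, other=pd.NA)
    df.to_csv(path, index_label="ril_id", na_rep="NA")


def read_genotype_csv(path, marker_map: MarkerMap) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="ril_id")
    if list(df.columns) != list(marker_map.marker_id):
        raise SchemaError("genotype columns do not match the marker map")
    dosages = df.to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    return GenotypeMatrix(tuple(df.index.astype(str)), marker_map, dosages)


def write_ped_map(geno: GenotypeMatrix, prefix) -> None:
    """PLINK-style .ped/.map: biallelic A/B coding, missing = '0 0'."""
    prefix = Path(prefix)
    code = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, rid in enumerate(geno.ril_ids):
            alleles = " ".join(code[int(d)] for d in geno.dosages[i])
            fh.write(f"FAM1 {rid} 0 0 0 -9 {alleles}\n")
    mm = geno.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(len(mm)):
            fh.write(f"{mm.chromosome[j]} {mm.marker_id[j]} "
                     f"{mm.position_cM[j]:.6f} {mm.position_bp[j]}\n")


def write_phenotype_csv(pheno: PhenotypeTable, path) -> None:
    pheno.df.to_csv(path, index=False)


def read_phenotype_csv(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path))


def write_architecture_json(arch: TraitArchitecture, path) -> None:
    payload = {
        "mu": arch.mu,
        "additive_qtl": [[i, b] for i, b in arch.additive_qtl],
        "epistatic_pairs": [[i, j, e, rule]
                            for i, j, e, rule in arch.epistatic_pairs],
        "env_effects": list(arch.env_effects),
        "target_h2": arch.target_h2,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_architecture_json(path) -> TraitArchitecture:
    with open(path) as fh:
        payload = json.load(fh)
    return TraitArchitecture(
        mu=payload["mu"],
        additive_qtl=tuple((int(i), float(b))
                           for i, b in payload["additive_qtl"]),
        epistatic_pairs=tuple((int(i), int(j), float(e), rule)
                              for i, j, e, rule in payload["epistatic_pairs"]),
        env_effects=tuple(payload["env_effects"]),
        target_h2=payload["target_h2"],
    )
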