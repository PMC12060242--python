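"""Simulation of biparental RIL populations with known trait architecture.

Generates marker maps, BC1S4-style recombinant inbred lines (one backcross to
the recurrent parent, then repeated selfing by single-seed descent), additive
and epistatic trait architectures, two-environment phenotypes, and missing-call
patterns. Dosages count the donor-parent allele, so the recurrent parent is
all-zero and Mendelian expectations (donor allele frequency 1/4 after one
backcross, residual heterozygosity 1/2^(s+1) after s selfings) are checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SchemaError

#: Sentinel for a missing marker call in dosage matrices.
MISSING: int = -1

_EPISTATIC_RULES = ("product", "complementary")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerMap:
    """Ordered genetic map: one row per marker.

    Within each chromosome ``position_bp`` is strictly increasing and
    ``position_cM`` is non-decreasing; marker ids are unique.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    position_cM: np.ndarray

    def __post_init__(self):
        mid = np.asarray(self.marker_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        bp = np.asarray(self.position_bp, dtype=np.int64)
        cm = np.asarray(self.position_cM, dtype=float)
        if not (len(mid) == len(chrom) == len(bp) == len(cm)):
            raise SchemaError("map columns have unequal lengths")
        if len(np.unique(mid)) != len(mid):
            raise SchemaError("marker ids are not unique")
        if np.any(chrom < 1) or np.any(bp < 0) or np.any(cm < 0):
            raise InvalidParameterError("chromosome >= 1 and positions >= 0 required")
        for c in np.unique(chrom):
            sel = chrom == c
            if np.any(np.diff(bp[sel]) <= 0):
                raise SchemaError(f"bp positions not strictly increasing on chromosome {c}")
            if np.any(np.diff(cm[sel]) < 0):
                raise SchemaError(f"cM positions decreasing on chromosome {c}")
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", bp)
        object.__setattr__(self, "position_cM", cm)

    def __len__(self) -> int:
        return len(self.marker_id)

    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chrom_indices(self, chrom: int) -> np.ndarray:
        """Column indices of the markers on one chromosome, in map order."""
        return np.flatnonzero(self.chromosome == chrom)

    def subset(self, indices: Sequence[int]) -> "MarkerMap":
        idx = np.asarray(indices, dtype=np.int64)
        return MarkerMap(
            self.marker_id[idx], self.chromosome[idx],
            self.position_bp[idx], self.position_cM[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_id,
            "chromosome": self.chromosome,
            "position_bp": self.position_bp,
            "position_cM": self.position_cM,
        })


@dataclass(frozen=True)
class GenotypeMatrix:
    """RIL x SNP donor-allele dosage matrix with :data:`MISSING` sentinel."""

    ril_ids: tuple
    markers: MarkerMap
    dosages: np.ndarray

    def __post_init__(self):
        ids = tuple(str(r) for r in self.ril_ids)
        dos = np.asarray(self.dosages, dtype=np.int8)
        if dos.ndim != 2 or dos.shape != (len(ids), len(self.markers)):
            raise SchemaError(
                f"dosages shape {dos.shape} != ({len(ids)}, {len(self.markers)})")
        valid = np.isin(dos, (0, 1, 2, MISSING))
        if not valid.all():
            raise SchemaError("dosage entries must be in {0,1,2,MISSING}")
        object.__setattr__(self, "ril_ids", ids)
        object.__setattr__(self, "dosages", dos)

    @property
    def n_ril(self) -> int:
        return len(self.ril_ids)

    @property
    def n_marker(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset_markers(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=np.int64)
        return GenotypeMatrix(self.ril_ids, self.markers.subset(idx),
                              self.dosages[:, idx])

    def subset_rils(self, row_indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(row_indices, dtype=np.int64)
        return GenotypeMatrix(tuple(self.ril_ids[i] for i in idx),
                              self.markers, self.dosages[idx])


@dataclass(frozen=True)
class TraitArchitecture:
    """Ground-truth genetic architecture of one simulated trait.

    ``additive_qtl`` holds (marker index, effect); ``epistatic_pairs`` holds
    (i, j, effect, rule) with rule in {"product", "complementary"}:

    * product: effect * (x_i - 1) * (x_j - 1)
    * complementary: effect * 1[x_i >= 1 and x_j >= 1]
    """

    mu: float
    additive_qtl: tuple
    epistatic_pairs: tuple
    env_effects: tuple
    target_h2: float

    def __post_init__(self):
        if not (0.0 < self.target_h2 <= 1.0):
            raise InvalidParameterError("target_h2 must be in (0, 1]")
        for i, j, _, rule in self.epistatic_pairs:
            if i == j:
                raise InvalidParameterError("epistatic pair with i == j")
            if rule not in _EPISTATIC_RULES:
                raise InvalidParameterError(f"unknown epistatic rule {rule!r}")

    def qtl_indices(self) -> np.ndarray:
        """All causal marker indices (additive and epistatic), sorted, unique."""
        idx = [i for i, _ in self.additive_qtl]
        for i, j, _, _ in self.epistatic_pairs:
            idx.extend((i, j))
        return np.unique(np.asarray(idx, dtype=np.int64))

    def genetic_values(self, dosages: np.ndarray) -> np.ndarray:
        """Closed-form genetic value g for each row of a complete dosage matrix."""
        X = np.asarray(dosages, dtype=float)
        g = np.full(X.shape[0], float(self.mu))
        for idx, beta in self.additive_qtl:
            g += beta * X[:, idx]
        for i, j, eff, rule in self.epistatic_pairs:
            if rule == "product":
                g += eff * (X[:, i] - 1.0) * (X[:, j] - 1.0)
            else:  # complementary
                g += eff * ((X[:, i] >= 1) & (X[:, j] >= 1))
        return g


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format phenotype records with optional ground-truth genetic value."""

    df: pd.DataFrame = field(repr=False)

    _COLUMNS = ("ril_id", "env", "trait", "value")

    def __post_init__(self):
        df = self.df
        for col in self._COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"phenotype table missing column {col!r}")
        if df.duplicated(subset=["ril_id", "env", "trait"]).any():
            raise SchemaError("duplicate (ril_id, env, trait) record")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_marker_map(n_chrom: int, markers_per_chrom: int,
                        chrom_length_bp: int, chrom_length_cM: float,
                        seed: int) -> MarkerMap:
    """Uniform-random marker positions, cM proportional to bp."""
    if n_chrom < 1 or markers_per_chrom < 1:
        raise InvalidParameterError("counts must be positive")
    if chrom_length_bp <= 0 or chrom_length_cM <= 0:
        raise InvalidParameterError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    ids, chroms, bps, cms = [], [], [], []
    for c in range(1, n_chrom + 1):
        if markers_per_chrom >= chrom_length_bp:
            raise InvalidParameterError("more markers than distinct bp positions")
        bp = np.unique(rng.integers(1, chrom_length_bp, size=markers_per_chrom))
        while len(bp) < markers_per_chrom:  # resolve duplicate draws
            extra = rng.integers(1, chrom_length_bp,
                                 size=markers_per_chrom - len(bp))
            bp = np.unique(np.concatenate([bp, extra]))
        cm = bp / chrom_length_bp * chrom_length_cM
        ids.extend(f"chr{c}_m{k}" for k in range(markers_per_chrom))
        chroms.extend([c] * markers_per_chrom)
        bps.append(bp)
        cms.append(cm)
    return MarkerMap(np.array(ids, dtype=object), np.array(chroms),
                     np.concatenate(bps), np.concatenate(cms))


def _gamete(hap0: np.ndarray, hap1: np.ndarray, marker_map: MarkerMap,
            chrom_slices: list, rng: np.random.Generator) -> np.ndarray:
    """One meiotic product: Haldane crossovers (Poisson on cM, no interference)."""
    out = np.empty_like(hap0)
    for sel, cm, span in chrom_slices:
        n_xo = rng.poisson(span / 100.0)
        phase0 = rng.integers(0, 2)
        if n_xo == 0:
            phase = np.full(cm.shape, phase0)
        else:
            xo = np.sort(rng.uniform(cm[0] if len(cm) else 0.0, cm[-1], size=n_xo)) \
                if span > 0 else np.empty(0)
            phase = (phase0 + np.searchsorted(xo, cm, side="right")) % 2
        out[sel] = np.where(phase == 0, hap0[sel], hap1[sel])
    return out


def simulate_ril_population(marker_map: MarkerMap, n_ril: int,
                            n_backcross: int = 1, n_self: int = 4,
                            seed: int = 0, ril_prefix: str = "RIL") -> GenotypeMatrix:
    """Simulate a biparental RIL population (default pedigree BC1S4).

    The F1 (donor haplotype x recurrent haplotype) is backcrossed
    ``n_backcross`` times to the all-zero recurrent parent, then advanced
    ``n_self`` generations by single-seed descent. Dosage = donor allele count.
    """
    if len(marker_map) == 0:
        raise InvalidParameterError("marker map is empty")
    if n_ril < 1:
        raise InvalidParameterError("n_ril must be >= 1")
    rng = np.random.default_rng(seed)
    p = len(marker_map)
    chrom_slices = []
    for c in marker_map.chromosomes():
        sel = marker_map.chrom_indices(c)
        cm = marker_map.position_cM[sel]
        span = float(cm[-1] - cm[0]) if len(cm) > 1 else 0.0
        chrom_slices.append((sel, cm, span))
    donor = np.ones(p, dtype=np.int8)
    recurrent = np.zeros(p, dtype=np.int8)
    dosages = np.empty((n_ril, p), dtype=np.int8)
    for r in range(n_ril):
        h0, h1 = donor, recurrent  # the F1
        for _ in range(n_backcross):
            h0, h1 = _gamete(h0, h1, marker_map, chrom_slices, rng), recurrent
        for _ in range(n_self):
            new0 = _gamete(h0, h1, marker_map, chrom_slices, rng)
            new1 = _gamete(h0, h1, marker_map, chrom_slices, rng)
            h0, h1 = new0, new1
        dosages[r] = h0 + h1
    ril_ids = tuple(f"{ril_prefix}{r:04d}" for r in range(n_ril))
    return GenotypeMatrix(ril_ids, marker_map, dosages)


def assign_trait_architecture(marker_map: MarkerMap, n_additive_qtl: int,
                              n_epistatic_pairs: int, effect_scale: float,
                              env_effect_sizes: Sequence[float],
                              target_h2: float, seed: int,
                              mu: float = 0.0,
                              epistatic_rule: str = "product") -> TraitArchitecture:
    """Sample a ground-truth architecture: distinct QTL, zero-mean effects."""
    p = len(marker_map)
    needed = n_additive_qtl + 2 * n_epistatic_pairs
    if n_additive_qtl < 0 or n_epistatic_pairs < 0:
        raise InvalidParameterError("QTL counts must be >= 0")
    if needed > p:
        raise InvalidParameterError(f"{needed} QTL indices requested, only {p} markers")
    if epistatic_rule not in _EPISTATIC_RULES:
        raise InvalidParameterError(f"unknown epistatic rule {epistatic_rule!r}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(p, size=needed, replace=False)
    add_idx = idx[:n_additive_qtl]
    epi_idx = idx[n_additive_qtl:]
    additive = tuple((int(i), float(rng.normal(0.0, effect_scale))) for i in add_idx)
    pairs = []
    for k in range(n_epistatic_pairs):
        i, j = int(epi_idx[2 * k]), int(epi_idx[2 * k + 1])
        pairs.append((i, j, float(rng.normal(0.0, effect_scale)), epistatic_rule))
    return TraitArchitecture(mu=float(mu), additive_qtl=additive,
                             epistatic_pairs=tuple(pairs),
                             env_effects=tuple(float(e) for e in env_effect_sizes),
                             target_h2=float(target_h2))


def simulate_phenotypes(geno: GenotypeMatrix, architecture: TraitArchitecture,
                        environments: int = 2, seed: int = 0,
                        trait: str = "trait") -> PhenotypeTable:
    """Phenotype = genetic value + environment main effect + residual.

    The residual variance is set so that Var(g)/(Var(g)+Var(e)) equals the
    architecture's target heritability across the simulated population.
    """
    if environments < 1:
        raise InvalidParameterError("environments must be >= 1")
    if environments > len(architecture.env_effects):
        raise InvalidParameterError("more environments than env_effects entries")
    qtl = architecture.qtl_indices()
    if len(qtl) and qtl.max() >= geno.n_marker:
        raise InvalidParameterError("architecture indexes markers beyond the panel")
    if geno.missing_mask().any():
        raise InvalidParameterError("phenotype simulation requires complete genotypes")
    rng = np.random.default_rng(seed)
    g = architecture.genetic_values(geno.dosages)
    var_g = float(np.var(g))
    h2 = architecture.target_h2
    sigma_e = np.sqrt(var_g * (1.0 - h2) / h2) if var_g > 0 else 0.0
    frames = []
    for e in range(environments):
        eps = rng.normal(0.0, sigma_e, size=geno.n_ril) if sigma_e > 0 else 0.0
        frames.append(pd.DataFrame({
            "ril_id": list(geno.ril_ids),
            "env": f"E{e + 1}",
            "trait": trait,
            "value": g + architecture.env_effects[e] + eps,
            "genetic_value": g,
        }))
    return PhenotypeTable(pd.concat(frames, ignore_index=True))


def inject_missing(geno: GenotypeMatrix, overall_rate: float,
                   high_missing_snp_fraction: float = 0.0,
                   seed: int = 0, high_rate: float = 0.2) -> GenotypeMatrix:
    """Set entries to MISSING at ``overall_rate``; a fraction of SNP columns
    gets the elevated ``high_rate`` so the >10% missingness filter has work."""
    for name, rate in (("overall_rate", overall_rate),
                       ("high_missing_snp_fraction", high_missing_snp_fraction),
                       ("high_rate", high_rate)):
        if not (0.0 <= rate <= 1.0):
            raise InvalidParameterError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n, p = geno.dosages.shape
    col_rate = np.full(p, overall_rate)
    n_high = int(round(high_missing_snp_fraction * p))
    if n_high:
        col_rate[rng.choice(p, size=n_high, replace=False)] = high_rate
    mask = rng.random((n, p)) < col_rate[None, :]
    if not mask.any():
        return geno
    dosages = geno.dosages.copy()
    dosages[mask] = MISSING
    return GenotypeMatrix(geno.ril_ids, geno.markers, dosages)
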