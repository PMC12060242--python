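"""Data-cleaning chain: missingness filter, two imputation methods, windowed
LD pruning, environment concatenation, and randomized train/test splits."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seeds import stable_seed
from .errors import (EmptyPanelError, InvalidParameterError,
                     ReferentialIntegrityError, SchemaError)
from .synthetic_data import MISSING, GenotypeMatrix, MarkerMap, PhenotypeTable


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """One randomized train/test partition: fraction, replicate index, seed."""

    train_fraction: float
    replicate: int = 0
    seed: int = 0
    by_ril: bool = False  # split whole RILs instead of records (off by default)

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise InvalidParameterError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class PrunedPanel:
    """Result of LD pruning: kept marker indices plus a removal log."""

    kept: np.ndarray
    removal_log: pd.DataFrame = field(repr=False)  # removed, partner, r2

    def __post_init__(self):
        object.__setattr__(self, "kept", np.asarray(self.kept, dtype=np.int64))


@dataclass(frozen=True)
class FeatureTable:
    """Model-ready design: one row per phenotype record.

    Columns are the marker dosages followed by a single binary environment
    indicator; the response is the trait value.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple
    ril_ids: tuple
    envs: tuple
    trait: str
    genetic_values: Optional[np.ndarray] = None

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0] or X.shape[1] != len(self.feature_names):
            raise SchemaError("feature table shapes do not line up")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_markers(self) -> int:
        return self.X.shape[1] - 1  # last column is the environment indicator


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_missing_snps(geno: GenotypeMatrix,
                        max_missing: float = 0.10) -> GenotypeMatrix:
    """Drop SNP columns whose missing fraction strictly exceeds ``max_missing``.

    A column at exactly the threshold is retained ("more than 10%" semantics).
    """
    if geno.n_marker == 0 or geno.n_ril == 0:
        raise InvalidParameterError("genotype matrix is empty")
    frac = geno.missing_mask().mean(axis=0)
    keep = np.flatnonzero(frac <= max_missing)
    if len(keep) == 0:
        raise EmptyPanelError("missingness filter would drop every SNP")
    if len(keep) == geno.n_marker:
        return geno
    return geno.subset_markers(keep)


def impute_most_frequent(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace MISSING entries by the column's modal dosage (tie: lower wins)."""
    dosages = geno.dosages.copy()
    mask = geno.missing_mask()
    if not mask.any():
        return geno
    for j in np.flatnonzero(mask.any(axis=0)):
        observed = dosages[~mask[:, j], j]
        if observed.size == 0:
            raise InvalidParameterError(
                f"column {j} is fully missing; run filter_missing_snps first")
        counts = np.bincount(observed, minlength=3)
        dosages[mask[:, j], j] = int(np.argmax(counts))  # argmax -> lowest on tie
    return GenotypeMatrix(geno.ril_ids, geno.markers, dosages)


def impute_flanking(geno: GenotypeMatrix,
                    marker_map: Optional[MarkerMap] = None):
    """Impute each missing call from its flanking markers on the same chromosome.

    If both flanks carry the same genotype it is copied; otherwise the
    genotype of the bp-closest flank wins (equidistant tie: left flank). At
    chromosome ends the single available flank is used. RILs with an entirely
    missing chromosome are removed and their ids returned.

    Returns ``(imputed genotype matrix, tuple of removed ril ids)``.
    """
    mm = marker_map if marker_map is not None else geno.markers
    if len(mm) != geno.n_marker:
        raise SchemaError("marker map does not cover the genotype columns")
    dosages = geno.dosages.copy()
    mask = geno.missing_mask()
    removed = []
    chrom_blocks = [(mm.chrom_indices(c), mm.position_bp[mm.chrom_indices(c)])
                    for c in mm.chromosomes()]
    for r in range(geno.n_ril):
        row_dead = False
        for cols, bp in chrom_blocks:
            miss = mask[r, cols]
            if not miss.any():
                continue
            if miss.all():
                row_dead = True
                break
            obs_pos = np.flatnonzero(~miss)
            vals = dosages[r, cols]
            for k in np.flatnonzero(miss):
                right_i = np.searchsorted(obs_pos, k)
                left = obs_pos[right_i - 1] if right_i > 0 else None
                right = obs_pos[right_i] if right_i < len(obs_pos) else None
                if left is None:
                    fill = vals[right]
                elif right is None:
                    fill = vals[left]
                elif vals[left] == vals[right]:
                    fill = vals[left]
                else:
                    dl = bp[k] - bp[left]
                    dr = bp[right] - bp[k]
                    fill = vals[left] if dl <= dr else vals[right]
                dosages[r, cols[k]] = fill
        if row_dead:
            removed.append(geno.ril_ids[r])
    keep_rows = [r for r in range(geno.n_ril) if geno.ril_ids[r] not in removed]
    out = GenotypeMatrix(tuple(geno.ril_ids[r] for r in keep_rows), geno.markers,
                         dosages[keep_rows])
    return out, tuple(removed)


def _pair_r2(col_i: np.ndarray, col_j: np.ndarray) -> Optional[float]:
    """Squared Pearson correlation of two dosage columns.

    Zero-variance columns have no defined r2; they count as duplicated
    (r2 = 1) only when exactly equal, else the pair is skipped (None).
    """
    vi, vj = col_i.std(), col_j.std()
    if vi == 0.0 or vj == 0.0:
        return 1.0 if np.array_equal(col_i, col_j) else None
    r = np.corrcoef(col_i, col_j)[0, 1]
    return float(r * r)


def ld_prune(geno: GenotypeMatrix, marker_map: Optional[MarkerMap] = None,
             r2_threshold: float = 0.8, window_bp: int = 30_000,
             step: int = 5) -> PrunedPanel:
    """Windowed LD pruning on a complete dosage matrix.

    Per chromosome, a window ``window_bp`` wide is anchored at the left-most
    surviving marker and advanced ``step`` surviving markers at a time; within
    a window, each pair with r2 > threshold loses its lower-MAF member
    (tie: the later-position SNP). Sweeps repeat until none removes anything,
    making the operation a fixed point of itself.
    """
    mm = marker_map if marker_map is not None else geno.markers
    if len(mm) != geno.n_marker:
        raise SchemaError("marker map does not cover the genotype columns")
    if geno.missing_mask().any():
        raise InvalidParameterError("LD pruning requires imputed (complete) genotypes")
    if step < 1 or window_bp <= 0:
        raise InvalidParameterError("step >= 1 and window_bp > 0 required")
    X = geno.dosages.astype(float)
    freqs = X.mean(axis=0) / 2.0
    maf = np.minimum(freqs, 1.0 - freqs)
    alive = np.ones(geno.n_marker, dtype=bool)
    log_rows = []

    def drop(i: int, j: int, r2: float):
        """Apply the removal rule to pair (i, j); positions i < j in map order."""
        if maf[i] < maf[j]:
            victim, partner = i, j
        elif maf[j] < maf[i]:
            victim, partner = j, i
        else:
            victim, partner = j, i  # tie: later position goes
        alive[victim] = False
        log_rows.append((mm.marker_id[victim], mm.marker_id[partner], r2))

    for c in mm.chromosomes():
        cols = mm.chrom_indices(c)
        changed = True
        while changed:
            changed = False
            surv = cols[alive[cols]]
            a = 0
            while a < len(surv):
                anchor_bp = mm.position_bp[surv[a]]
                in_win = surv[(mm.position_bp[surv] >= anchor_bp)
                              & (mm.position_bp[surv] <= anchor_bp + window_bp)]
                for ii in range(len(in_win)):
                    i = in_win[ii]
                    if not alive[i]:
                        continue
                    for jj in range(ii + 1, len(in_win)):
                        j = in_win[jj]
                        if not alive[i]:
                            break
                        if not alive[j]:
                            continue
                        r2 = _pair_r2(X[:, i], X[:, j])
                        if r2 is not None and r2 > r2_threshold:
                            drop(i, j, r2)
                            changed = True
                a += step
    kept = np.flatnonzero(alive)
    log = pd.DataFrame(log_rows, columns=["removed", "partner", "r2"])
    return PrunedPanel(kept=kept, removal_log=log)


def concat_environments(pheno: PhenotypeTable, geno: GenotypeMatrix,
                        trait: Optional[str] = None) -> FeatureTable:
    """One feature row per phenotype record: marker dosages + env indicator."""
    df = pheno.df
    traits = df["trait"].unique()
    if trait is None:
        if len(traits) != 1:
            raise InvalidParameterError(
                f"table has traits {list(traits)}; pass trait= to choose one")
        trait = traits[0]
    df = df[df["trait"] == trait]
    if len(df) == 0:
        raise InvalidParameterError(f"no records for trait {trait!r}")
    envs = sorted(df["env"].unique())
    if len(envs) > 2:
        raise InvalidParameterError("at most 2 environment levels supported")
    env_code = {e: float(i) for i, e in enumerate(envs)}
    row_of = {rid: i for i, rid in enumerate(geno.ril_ids)}
    rows, y, rids, envs_out, gvals = [], [], [], [], []
    has_g = "genetic_value" in df.columns
    for rec in df.itertuples(index=False):
        if rec.ril_id not in row_of:
            raise ReferentialIntegrityError(
                f"phenotype record references unknown RIL {rec.ril_id!r}")
        rows.append(row_of[rec.ril_id])
        y.append(rec.value)
        rids.append(rec.ril_id)
        envs_out.append(rec.env)
        if has_g:
            gvals.append(rec.genetic_value)
    X = np.column_stack([
        geno.dosages[rows].astype(float),
        np.array([env_code[e] for e in envs_out]),
    ])
    names = tuple(geno.markers.marker_id) + ("env",)
    return FeatureTable(X=X, y=np.array(y), feature_names=names,
                        ril_ids=tuple(rids), envs=tuple(envs_out), trait=trait,
                        genetic_values=np.array(gvals) if has_g else None)


def split_train_test(feature_table: FeatureTable, split_spec: SplitSpec):
    """Uniform random partition of records; reproducible from (seed, replicate)."""
    n = len(feature_table)
    if n == 0:
        raise InvalidParameterError("feature table is empty")
    rng = np.random.default_rng(stable_seed("split", split_spec.seed,
                                            split_spec.replicate))
    if split_spec.by_ril:
        rils = list(dict.fromkeys(feature_table.ril_ids))  # order-preserving
        n_train_r = int(round(split_spec.train_fraction * len(rils)))
        if n_train_r == 0 or n_train_r == len(rils):
            raise InvalidParameterError("split leaves train or test empty")
        perm = rng.permutation(len(rils))
        train_rils = {rils[i] for i in perm[:n_train_r]}
        train = np.array([i for i, r in enumerate(feature_table.ril_ids)
                          if r in train_rils], dtype=np.int64)
        test = np.array([i for i, r in enumerate(feature_table.ril_ids)
                         if r not in train_rils], dtype=np.int64)
    else:
        n_train = int(round(split_spec.train_fraction * n))
        if n_train == 0 or n_train == n:
            raise InvalidParameterError("split leaves train or test empty")
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
    return train, test
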