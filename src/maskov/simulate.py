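"""Synthetic pseudo-testcross progenies with known crossovers.

The generator emulates the shape of a shallow-GBS mapping study in an
outcrossing diploid: 71 progeny, seven linkage groups with the reference
map's lengths, thousands of uni-parental testcross SNPs, ~36% missing calls
with strong per-individual variance (depth varies between individuals), and
symmetric genotyping errors that manufacture spurious double recombinants.

Meiosis is modelled without crossover interference: per gamete and linkage
group the crossover count is Poisson(length_cM / 100) with breakpoints
uniform along the group.  Each individual's encoded vector is the parental
phase sequence cut at those breakpoints.  Degradation drops cells at a
per-individual rate drawn from a Beta distribution (mean/standard-deviation
parameterisation) and flips surviving calls with a fixed error
probability; a cell is never both missing and erroneous.

Every operation is deterministic under a fixed seed, and the paired
clean/observed matrices plus crossover and corruption masks form a truth
set for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, decode_values, encode_group
from .mapstats import count_recombinations

__all__ = [
    "HERITAGE_LG_LENGTHS_CM",
    "SimulationParams",
    "TruthSet",
    "RecoveryMetrics",
    "simulate_clean",
    "degrade",
    "simulate_progeny",
    "evaluate_recovery",
]

#: linkage-group lengths (cM) of the seven-group reference maternal map
HERITAGE_LG_LENGTHS_CM: tuple[float, ...] = (87.6, 46.4, 73.6, 78.5, 53.1, 68.4, 55.1)


@dataclass(frozen=True)
class SimulationParams:
    """Study-shaped defaults for the synthetic progeny.

    n_individuals:
        Progeny size (71, the study's seedling count).
    lg_lengths_cM:
        Linkage-group lengths; default the seven maternal-map lengths.
    markers_per_lg:
        Markers per group (int applied to all groups, or one per group).
    missing_mean:
        Target overall missing fraction (0.36).
    missing_dispersion:
        Standard deviation of the per-individual missing rate (Beta
        distributed); 0.10 reproduces the strong between-individual spread
        of sequencing depth.  Must satisfy sd^2 < mean*(1-mean).
    error_rate:
        Per-call probability of a symmetric testcross-class flip among
        non-missing cells (0.02).
    seed:
        Base RNG seed; every operation is reproducible under it.
    """

    n_individuals: int = 71
    lg_lengths_cM: tuple[float, ...] = HERITAGE_LG_LENGTHS_CM
    markers_per_lg: int | tuple[int, ...] = 500
    missing_mean: float = 0.36
    missing_dispersion: float = 0.10
    error_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if any(L < 0 for L in self.lg_lengths_cM):
            raise ValueError("linkage-group lengths must be >= 0")
        for m in self.markers_per_list():
            if m < 2:
                raise ValueError("each group needs >= 2 markers")
        if not 0.0 <= self.missing_mean <= 1.0:
            raise ValueError("missing_mean must lie in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.missing_dispersion < 0:
            raise ValueError("missing_dispersion must be >= 0")

    def markers_per_list(self) -> list[int]:
        if isinstance(self.markers_per_lg, int):
            return [self.markers_per_lg] * len(self.lg_lengths_cM)
        if len(self.markers_per_lg) != len(self.lg_lengths_cM):
            raise ValueError("markers_per_lg must match lg_lengths_cM")
        return list(self.markers_per_lg)


@dataclass
class TruthSet:
    """Paired clean/observed matrices with the generating crossovers.

    ``crossovers`` has one row per individual x linkage group with the
    breakpoint positions (cM) and count; ``missing_mask``/``error_mask``
    are marker x individual booleans marking the introduced corruption
    (mutually exclusive by construction).  ``observed`` is ``None`` until
    :func:`degrade` fills it.
    """

    params: SimulationParams
    clean: GenotypeMatrix
    phases: np.ndarray
    marker_positions_cM: np.ndarray
    crossovers: pd.DataFrame
    observed: GenotypeMatrix | None = None
    missing_mask: np.ndarray | None = None
    error_mask: np.ndarray | None = None

    def true_crossover_counts(self) -> pd.Series:
        """Per-individual total crossover counts across all groups."""
        per = self.crossovers.groupby("individual", sort=False)["n_crossovers"].sum()
        return per.reindex(self.clean.individual_ids).fillna(0).astype(int)


def _lg_names(k: int) -> list[str]:
    return [f"LG{i + 1}" for i in range(k)]


def simulate_clean(params: SimulationParams, rng: np.random.Generator | None = None) -> TruthSet:
    """Generate the error-free, complete progeny matrix with known crossovers."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    markers_per = params.markers_per_list()
    lgs = _lg_names(len(params.lg_lengths_cM))
    inds = [f"ind{j + 1:03d}" for j in range(params.n_individuals)]

    marker_ids: list[str] = []
    lg_col: list[str] = []
    order_col: list[int] = []
    pos_col: list[float] = []
    enc_blocks: list[np.ndarray] = []
    co_rows: list[dict] = []

    for g, (lg, L, m) in enumerate(zip(lgs, params.lg_lengths_cM, markers_per)):
        pos = np.sort(rng.uniform(0.0, L, size=m)) if L > 0 else np.zeros(m)
        marker_ids.extend(f"{lg}_M{i + 1:04d}" for i in range(m))
        lg_col.extend([lg] * m)
        order_col.extend(range(m))
        pos_col.extend(pos)
        enc = np.empty((m, params.n_individuals), dtype=np.int8)
        for j, ind in enumerate(inds):
            n_co = rng.poisson(L / 100.0)
            breaks = np.sort(rng.uniform(0.0, L, size=n_co)) if L > 0 else np.empty(0)
            start = 1 if rng.random() < 0.5 else -1
            # parity of crossovers below each marker position decides the phase
            flips = np.searchsorted(breaks, pos)
            enc[:, j] = start * np.where(flips % 2 == 0, 1, -1)
            co_rows.append(
                {
                    "individual": ind,
                    "lg": lg,
                    "n_crossovers": int(n_co),
                    "positions_cM": ",".join(f"{b:.4f}" for b in breaks),
                }
            )
        enc_blocks.append(enc)

    encoded = np.vstack(enc_blocks)
    phases = rng.choice(np.array([1, -1], dtype=np.int8), size=len(marker_ids))
    calls = decode_values(encoded, phases[:, None] * np.ones_like(encoded))
    clean = GenotypeMatrix(
        calls=calls,
        marker_ids=marker_ids,
        linkage_group=np.array(lg_col, dtype=object),
        order_index=np.array(order_col, dtype=np.int64),
        individual_ids=inds,
        phases=phases,
    )
    return TruthSet(
        params=params,
        clean=clean,
        phases=phases,
        marker_positions_cM=np.array(pos_col),
        crossovers=pd.DataFrame(co_rows),
    )


def degrade(truth: TruthSet, rng: np.random.Generator | None = None) -> TruthSet:
    """Fill the observed matrix by dropping and flipping cells in place.

    Per-individual missing rates are Beta distributed with the configured
    mean and standard deviation; cells are dropped independently at that
    rate, then surviving calls are flipped between the two testcross
    classes with probability ``error_rate``.
    """
    params = truth.params
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    n_mark, n_ind = truth.clean.calls.shape

    m, sd = params.missing_mean, params.missing_dispersion
    if m <= 0:
        rates = np.zeros(n_ind)
    elif sd == 0 or m >= 1:
        rates = np.full(n_ind, m)
    else:
        var = sd * sd
        if var >= m * (1 - m):
            raise ValueError("missing_dispersion too large for a Beta distribution")
        kappa = m * (1 - m) / var - 1.0
        rates = rng.beta(m * kappa, (1 - m) * kappa, size=n_ind)

    missing_mask = rng.random((n_mark, n_ind)) < rates[None, :]
    error_mask = (~missing_mask) & (rng.random((n_mark, n_ind)) < params.error_rate)

    calls = truth.clean.calls.copy()
    from .model import HET, HOM, MISSING

    calls[missing_mask] = MISSING
    flip = error_mask & (truth.clean.calls == HET)
    calls[flip] = HOM
    flip = error_mask & (truth.clean.calls == HOM)
    calls[flip] = HET

    truth.observed = GenotypeMatrix(
        calls=calls,
        marker_ids=list(truth.clean.marker_ids),
        linkage_group=truth.clean.linkage_group.copy(),
        order_index=truth.clean.order_index.copy(),
        individual_ids=list(truth.clean.individual_ids),
        phases=truth.phases.copy(),
    )
    truth.missing_mask = missing_mask
    truth.error_mask = error_mask
    return truth


def simulate_progeny(params: SimulationParams) -> TruthSet:
    """Convenience: simulate_clean followed by degrade under the same seed."""
    return degrade(simulate_clean(params))


@dataclass
class RecoveryMetrics:
    """How well imputation recovered the simulated truth."""

    genotype_recovery_pct: float  # masked-missing cells restored to the clean call
    error_correction_pct: float  # flipped cells restored to the clean call
    crossover_bias: float  # (mean detected - mean true)/mean true
    mean_true_crossovers: float
    mean_detected_crossovers: float
    edge_position_errors: np.ndarray  # |marker-interval offset| for matched edges


def evaluate_recovery(truth: TruthSet, imputed: GenotypeMatrix) -> RecoveryMetrics:
    """Score an imputed matrix against the simulator's truth set.

    Recovery is computed over the cells that were masked missing (a cell
    still missing after imputation counts as unrecovered); error correction
    over the flipped cells.  Crossover bias compares the mean per-individual
    sign-change count of the imputed matrix with the true crossover mean.
    Edge position error matches detected and true breakpoints per
    individual x group (when counts agree) and reports the absolute offset
    in marker intervals.
    """
    if truth.observed is None or truth.missing_mask is None:
        raise ValueError("truth set has no observed part; run degrade first")
    if imputed.calls.shape != truth.clean.calls.shape:
        raise ValueError("imputed matrix shape does not match the truth set")

    mm = truth.missing_mask
    recov = float(np.mean(imputed.calls[mm] == truth.clean.calls[mm]) * 100) if mm.any() else 100.0
    em = truth.error_mask
    corr = float(np.mean(imputed.calls[em] == truth.clean.calls[em]) * 100) if em.any() else 100.0

    true_counts = truth.true_crossover_counts().to_numpy()
    mean_true = float(true_counts.mean())
    phases = truth.phases
    detected = np.zeros(imputed.n_individuals, dtype=np.int64)
    pos_errors: list[int] = []
    for g in imputed.groups():
        enc, _, rows = encode_group(imputed, phases, g)
        clean_enc, _, _ = encode_group(truth.clean, phases, g)
        mpos = truth.marker_positions_cM[rows]
        co_g = truth.crossovers[truth.crossovers["lg"] == g].set_index("individual")
        for j, ind in enumerate(imputed.individual_ids):
            k = count_recombinations(enc[:, j])
            detected[j] += k
            # match breakpoints when the count is right
            true_pos = co_g.loc[ind, "positions_cM"]
            breaks = [float(x) for x in true_pos.split(",")] if true_pos else []
            if k == len(breaks) and k > 0:
                v = enc[:, j]
                nz = np.flatnonzero(v)
                vals = v[nz]
                det_iv = nz[np.flatnonzero(vals[1:] != vals[:-1])]  # edge after this index
                true_iv = np.clip(np.searchsorted(mpos, breaks) - 1, 0, len(mpos) - 2)
                pos_errors.extend(np.abs(det_iv - np.sort(true_iv)).tolist())
    mean_det = float(detected.mean())
    bias = (mean_det - mean_true) / mean_true if mean_true > 0 else 0.0
    return RecoveryMetrics(
        genotype_recovery_pct=recov,
        error_correction_pct=corr,
        crossover_bias=float(bias),
        mean_true_crossovers=mean_true,
        mean_detected_crossovers=mean_det,
        edge_position_errors=np.array(pos_errors, dtype=np.int64),
    )
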