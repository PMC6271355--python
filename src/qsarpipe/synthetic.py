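"""Synthetic QSAR-like datasets with known ground truth.

Real QSAR matrices are wide: thousands of computed descriptors of which only a
handful carry signal, many are noisy copies of one another, and the rest are
activity-independent noise.  :func:`generate_qsar_dataset` emulates exactly
that statistical structure — informative descriptors drawn from a correlated
multivariate normal, activity as a linear combination of them plus Gaussian
noise, redundant columns as jittered copies, pure-noise columns independent —
so every pipeline stage (correlation screening, PCA, HCA, PLS/PCR) can be
exercised against a known answer.

:func:`make_paperlike_dataset` mimics the shape of the artemisinin training
table instead: 21 compounds, 4 descriptors, and a bimodal activity (10 values
near zero, 11 spread over [0.3, 2.4]) produced by a two-class mean shift in
descriptor space, for clustering and classification smoke tests.

Randomness is a single seeded stream per dataset; per-column-block substreams
are derived deterministically from it so that adding noise columns does not
perturb the informative block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import CompoundRecord, QSARDataError, QSARDataset

__all__ = ["SyntheticSpec", "GroundTruth", "generate_qsar_dataset", "make_paperlike_dataset"]

#: Default pairwise correlation within the informative descriptor block.
DEFAULT_INFORMATIVE_CORRELATION = 0.3


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic compound x descriptor matrix with activity.

    ``true_coefficients`` act on the standardized informative descriptors;
    ``noise_sd`` is the activity-noise standard deviation in activity units;
    ``redundancy_sd`` the jitter of redundant copies in descriptor units.
    """

    n_compounds: int = 100
    n_informative: int = 4
    n_redundant: int = 0
    n_noise: int = 0
    true_coefficients: tuple[float, ...] = (-0.3, -0.4, 0.4, 0.3)
    noise_sd: float = 0.3
    redundancy_sd: float = 0.3
    informative_correlation: float = DEFAULT_INFORMATIVE_CORRELATION
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_compounds, self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise QSARDataError("all counts must be non-negative")
        if self.true_coefficients and self.n_informative < 1:
            raise QSARDataError("true_coefficients given but n_informative < 1")
        if len(self.true_coefficients) != self.n_informative:
            raise QSARDataError(
                f"need {self.n_informative} true coefficients, got {len(self.true_coefficients)}"
            )
        if self.noise_sd < 0 or self.redundancy_sd < 0:
            raise QSARDataError("noise_sd and redundancy_sd must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually used; enough to compute oracle quantities.

    The attainable R-squared of any linear model on this data is
    Var(X beta) / (Var(X beta) + noise_sd^2), exposed as :meth:`oracle_r2`.
    """

    informative_names: list[str]
    coefficients: np.ndarray
    noise_sd: float
    signal_variance: float
    seed: int

    def oracle_r2(self) -> float:
        total = self.signal_variance + self.noise_sd**2
        return self.signal_variance / total if total > 0 else 0.0


def _informative_covariance(m: int, rho: float) -> np.ndarray:
    cov = np.full((m, m), rho)
    np.fill_diagonal(cov, 1.0)
    if m and np.linalg.eigvalsh(cov).min() < -1e-12:
        raise QSARDataError(
            f"informative correlation {rho} gives a non-positive-semidefinite structure"
        )
    return cov


def generate_qsar_dataset(spec: SyntheticSpec) -> tuple[QSARDataset, GroundTruth]:
    """Draw a dataset per the spec; fully reproducible from ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    ss_info, ss_act, ss_red, ss_noise = root.spawn(4)
    n, m_inf = spec.n_compounds, spec.n_informative

    rng = np.random.default_rng(ss_info)
    cov = _informative_covariance(m_inf, spec.informative_correlation)
    x_inf = (
        rng.multivariate_normal(np.zeros(m_inf), cov, size=n, method="cholesky")
        if m_inf
        else np.empty((n, 0))
    )

    beta = np.asarray(spec.true_coefficients, dtype=float)
    signal = x_inf @ beta if m_inf else np.zeros(n)
    activity = signal + np.random.default_rng(ss_act).normal(0.0, spec.noise_sd, size=n)

    rng_red = np.random.default_rng(ss_red)
    redundant = np.empty((n, spec.n_redundant))
    red_parents = []
    for j in range(spec.n_redundant):
        parent = j % m_inf if m_inf else 0
        red_parents.append(parent)
        source = x_inf[:, parent] if m_inf else np.zeros(n)
        redundant[:, j] = source + rng_red.normal(0.0, spec.redundancy_sd, size=n)

    noise = np.random.default_rng(ss_noise).standard_normal((n, spec.n_noise))

    names = (
        [f"inf_{j + 1}" for j in range(m_inf)]
        + [f"red_{j + 1}_of_inf_{red_parents[j] + 1}" for j in range(spec.n_redundant)]
        + [f"noise_{j + 1}" for j in range(spec.n_noise)]
    )
    x = np.column_stack([x_inf, redundant, noise]) if names else np.empty((n, 0))
    compounds = [
        CompoundRecord(
            compound_id=f"s{i + 1}",
            descriptor_values=dict(zip(names, x[i])),
            log_ra=float(activity[i]),
        )
        for i in range(n)
    ]
    truth = GroundTruth(
        informative_names=names[:m_inf],
        coefficients=beta,
        noise_sd=spec.noise_sd,
        signal_variance=float(beta @ cov @ beta) if m_inf else 0.0,
        seed=spec.seed,
    )
    return QSARDataset(names, compounds), truth


# class structure mirroring the artemisinin table: 10 inactive / 11 active,
# with per-descriptor class-mean shifts matching the standardized separation
# measured on that table (in pooled within-class sd units)
_PAPERLIKE_N_POTENT = 11
_PAPERLIKE_N_LESS = 10
_PAPERLIKE_SHIFT = np.array([-1.14, -2.13, 2.94, 0.85])
_PAPERLIKE_NAMES = ["desc_1", "desc_2", "desc_3", "desc_4"]


def make_paperlike_dataset(seed: int, noise_sd: float = 0.15) -> QSARDataset:
    """A 21 x 4 two-class dataset shaped like the artemisinin training table.

    Eleven "potent" compounds get descriptor means shifted by the class
    separation observed in the real table (about -1.1 to +2.9 within-class
    sd per descriptor) and activities spread over [0.3, 2.4]; ten "less
    potent" compounds sit near activity 0 (jittered by ``noise_sd``).  Ground-truth
    class membership is recoverable from the sign of the activity.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = np.array([1] * _PAPERLIKE_N_POTENT + [0] * _PAPERLIKE_N_LESS)
    rng.shuffle(labels)
    n = len(labels)
    x = rng.standard_normal((n, 4)) + np.outer(labels, _PAPERLIKE_SHIFT)
    activity = np.where(
        labels == 1,
        rng.uniform(0.3, 2.4, size=n),
        np.abs(rng.normal(0.0, noise_sd, size=n)) * -1.0,  # at or below zero
    )
    compounds = [
        CompoundRecord(
            compound_id=str(i + 1),
            descriptor_values=dict(zip(_PAPERLIKE_NAMES, x[i])),
            log_ra=float(activity[i]),
        )
        for i in range(n)
    ]
    return QSARDataset(list(_PAPERLIKE_NAMES), compounds)
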