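"""SEM model specification and RAM parameterisation.

Models are written in a compact lavaan-style text syntax::

    SVD  =~ wmh_cuberoot + epvs_bg + cmb_any + lacune_any
    RISK =~ education + sbp + whr + alcohol + hearing_loss + tbi
    SVD  ~ RISK + age
    RISK ~ age + sex
    wmh_cuberoot ~~ epvs_bg        # residual covariance (optional)

``=~`` defines a latent variable by its indicators, ``~`` a regression,
``~~`` a (residual) covariance.  A term may carry a fixed coefficient
(``1*wmh_cuberoot``).

Internally the model is held in RAM (reticular action model) form over the
full variable vector v = (observed, latent):

    v = A v + u,   Cov(u) = S,   E[u] = m
    Sigma = F (I - A)^-1 S (I - A)^-T F^T,   mu = F (I - A)^-1 m

where ``A`` holds directed edges (loadings, regressions), ``S`` symmetric
variances/covariances, ``m`` intercepts/means, and ``F`` selects the
observed rows.  Free parameters are tracked as (matrix, row, col) entries
with start values; variances are optimised on the log scale for positivity.

Identification defaults to fixing the first loading of each latent to 1
(marker identification); ``identification="std_lv"`` instead fixes each
latent (residual) variance to 1 and frees all loadings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Parameter", "ModelSpec", "SemSpecError"]


class SemSpecError(ValueError):
    """Malformed or unidentified model specification."""


@dataclass
class Parameter:
    matrix: str  # 'A' (directed), 'S' (symmetric), 'M' (mean/intercept)
    row: int
    col: int
    free: bool
    value: float  # start value if free, fixed value otherwise
    label: str
    is_variance: bool = False  # diagonal S entry -> log-parameterised


_TERM_RE = re.compile(r"^(?:([+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)\*)?([A-Za-z_][\w.]*)$")


def _parse_terms(rhs: str):
    terms = []
    for raw in rhs.split("+"):
        raw = raw.strip()
        if not raw:
            raise SemSpecError(f"empty term in {rhs!r}")
        m = _TERM_RE.match(raw)
        if not m:
            raise SemSpecError(f"cannot parse term {raw!r}")
        coef = float(m.group(1)) if m.group(1) is not None else None
        terms.append((coef, m.group(2)))
    return terms


class ModelSpec:
    """A parsed, identified SEM with its free-parameter bookkeeping."""

    def __init__(
        self,
        measurement: list[tuple[str, list[tuple[float | None, str]]]],
        regressions: list[tuple[str, list[tuple[float | None, str]]]],
        covariances: list[tuple[str, str, float | None]],
        observed_order: list[str] | None = None,
        identification: str = "marker",
        meanstructure: bool = False,
        default_exo_cov: bool = True,
    ):
        if identification not in ("marker", "std_lv"):
            raise SemSpecError(f"unknown identification {identification!r}")
        self.identification = identification
        self.meanstructure = meanstructure
        self.default_exo_cov = default_exo_cov
        self.latent_vars = [lv for lv, _ in measurement]
        if len(set(self.latent_vars)) != len(self.latent_vars):
            raise SemSpecError("duplicate latent definition")

        seen: list[str] = []
        for _, terms in measurement:
            for _, v in terms:
                if v not in seen:
                    seen.append(v)
        for out, terms in regressions:
            for v in [out] + [t[1] for t in terms]:
                if v not in seen:
                    seen.append(v)
        for a, b, _ in covariances:
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
        observed_seen = [v for v in seen if v not in self.latent_vars]
        if observed_order is None:
            self.observed_vars = observed_seen
        else:
            missing = set(observed_seen) - set(observed_order)
            if missing:
                raise SemSpecError(f"observed_order lacks variables {sorted(missing)}")
            self.observed_vars = list(observed_order)
        if not self.observed_vars:
            raise SemSpecError("model has no observed variables")

        self.names = self.observed_vars + self.latent_vars
        self._idx = {v: i for i, v in enumerate(self.names)}
        self.n_obs = len(self.observed_vars)
        self.n_total = len(self.names)

        # endogenous = appears as regression outcome or as an indicator
        endo = {out for out, _ in regressions}
        indicators = {v for _, terms in measurement for _, v in terms}
        self._endogenous = endo | indicators
        self._build(measurement, regressions, covariances)

    # ------------------------------------------------------------------ build
    def _build(self, measurement, regressions, covariances) -> None:
        params: list[Parameter] = []
        directed: set[tuple[int, int]] = set()
        symmetric: set[tuple[int, int]] = set()

        def add(p: Parameter):
            key = (p.row, p.col)
            if p.matrix == "A":
                if key in directed:
                    raise SemSpecError(f"duplicate edge {p.label}")
                directed.add(key)
            elif p.matrix == "S":
                key = (min(key), max(key))
                if key in symmetric:
                    raise SemSpecError(f"duplicate covariance {p.label}")
                symmetric.add(key)
            params.append(p)

        ix = self._idx
        for lv, terms in measurement:
            for k, (coef, ind) in enumerate(terms):
                if ind in self.latent_vars:
                    raise SemSpecError(f"latent {ind} cannot be an indicator")
                fixed_marker = (
                    coef is None and k == 0 and self.identification == "marker"
                )
                if coef is not None:
                    add(Parameter("A", ix[ind], ix[lv], False, coef, f"{lv}=~{ind}"))
                elif fixed_marker:
                    add(Parameter("A", ix[ind], ix[lv], False, 1.0, f"{lv}=~{ind}"))
                else:
                    add(Parameter("A", ix[ind], ix[lv], True, 0.7, f"{lv}=~{ind}"))
        for out, terms in regressions:
            for coef, pred in terms:
                free = coef is None
                add(
                    Parameter(
                        "A", ix[out], ix[pred], free, 0.0 if free else coef, f"{out}~{pred}"
                    )
                )
        for a, b, coef in covariances:
            i, j = ix[a], ix[b]
            is_var = i == j
            free = coef is None
            add(
                Parameter(
                    "S", i, j, free, (1.0 if is_var else 0.0) if free else coef,
                    f"{a}~~{b}", is_variance=is_var and free,
                )
            )

        # default variances: every variable gets a (residual) variance unless
        # explicitly specified; std_lv fixes latent variances to 1
        for v in self.names:
            i = ix[v]
            if (i, i) in symmetric:
                continue
            if v in self.latent_vars and self.identification == "std_lv":
                add(Parameter("S", i, i, False, 1.0, f"{v}~~{v}"))
            else:
                add(Parameter("S", i, i, True, 1.0, f"{v}~~{v}", is_variance=True))

        # default covariances among exogenous variables (lavaan-like)
        exo = [v for v in self.names if v not in self._endogenous]
        if self.default_exo_cov:
            for a_i in range(len(exo)):
                for b_i in range(a_i + 1, len(exo)):
                    i, j = ix[exo[a_i]], ix[exo[b_i]]
                    key = (min(i, j), max(i, j))
                    if key not in symmetric:
                        add(Parameter("S", i, j, True, 0.0, f"{exo[a_i]}~~{exo[b_i]}"))

        if self.meanstructure:
            for v in self.observed_vars:
                add(Parameter("M", ix[v], 0, True, 0.0, f"{v}~1"))
            # latent means/intercepts fixed at zero (implicit)

        self.parameters = params
        self.free_parameters = [p for p in params if p.free]
        self.n_free = len(self.free_parameters)
        self.exogenous_vars = exo
        self._check_identification()

    def _check_identification(self) -> None:
        p = self.n_obs
        n_moments = p * (p + 1) // 2 + (p if self.meanstructure else 0)
        self.df = n_moments - self.n_free
        if self.df < 0:
            raise SemSpecError(
                f"model not identified: {self.n_free} free parameters for "
                f"{n_moments} sample moments (df = {self.df})"
            )

    # ------------------------------------------------------------- text parse
    @classmethod
    def from_text(
        cls,
        text: str,
        observed_order: list[str] | None = None,
        identification: str = "marker",
        meanstructure: bool = False,
        default_exo_cov: bool = True,
    ) -> "ModelSpec":
        measurement, regressions, covariances = [], [], []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=~" in line:
                lhs, rhs = line.split("=~", 1)
                lv = lhs.strip()
                for name, terms in measurement:
                    if name == lv:
                        terms.extend(_parse_terms(rhs))
                        break
                else:
                    measurement.append((lv, _parse_terms(rhs)))
            elif "~~" in line:
                lhs, rhs = line.split("~~", 1)
                lhs = lhs.strip()
                for coef, v in _parse_terms(rhs):
                    covariances.append((lhs, v, coef))
            elif "~" in line:
                lhs, rhs = line.split("~", 1)
                regressions.append((lhs.strip(), _parse_terms(rhs)))
            else:
                raise SemSpecError(f"cannot parse line {raw!r}")
        return cls(
            measurement,
            regressions,
            covariances,
            observed_order=observed_order,
            identification=identification,
            meanstructure=meanstructure,
            default_exo_cov=default_exo_cov,
        )

    # -------------------------------------------------------------- theta ops
    def start_theta(self) -> np.ndarray:
        return np.array([p.value for p in self.free_parameters], dtype=float)

    def theta_labels(self) -> list[str]:
        return [p.label for p in self.free_parameters]

    def theta_from_dict(self, values: dict[str, float]) -> np.ndarray:
        theta = self.start_theta()
        labels = self.theta_labels()
        pos = {lab: i for i, lab in enumerate(labels)}
        for lab, v in values.items():
            if lab not in pos:
                raise KeyError(f"{lab!r} is not a free parameter ({labels})")
            theta[pos[lab]] = v
        return theta

    def matrices(self, theta: np.ndarray):
        """Full A, S, m at the given free-parameter vector."""
        t = self.n_total
        A = np.zeros((t, t))
        S = np.zeros((t, t))
        m = np.zeros(t)
        it = iter(theta)
        for p in self.parameters:
            val = next(it) if p.free else p.value
            if p.matrix == "A":
                A[p.row, p.col] = val
            elif p.matrix == "S":
                S[p.row, p.col] = val
                S[p.col, p.row] = val
            else:
                m[p.row] = val
        return A, S, m

    def implied_moments(self, theta: np.ndarray):
        """Model-implied covariance (and mean vector) of the observed variables."""
        A, S, m = self.matrices(theta)
        ident = np.eye(self.n_total)
        try:
            B = np.linalg.inv(ident - A)
        except np.linalg.LinAlgError as err:
            raise SemSpecError("(I - A) is singular for the given parameters") from err
        sigma_all = B @ S @ B.T
        sigma = sigma_all[: self.n_obs, : self.n_obs]
        mu = (B @ m)[: self.n_obs]
        return (sigma, mu) if self.meanstructure else (sigma, None)

    def implied_full_covariance(self, theta: np.ndarray) -> np.ndarray:
        """Implied covariance over observed *and* latent variables."""
        A, S, _ = self.matrices(theta)
        B = np.linalg.inv(np.eye(self.n_total) - A)
        return B @ S @ B.T

    def drop_parameter(self, label: str) -> "ModelSpec":
        """A copy of the model with one free directed edge removed (fixed 0)."""
        import copy

        new = copy.deepcopy(self)
        hit = [p for p in new.parameters if p.label == label and p.free]
        if not hit:
            raise SemSpecError(f"no free parameter {label!r} to drop")
        new.parameters.remove(hit[0])
        new.free_parameters = [p for p in new.parameters if p.free]
        new.n_free = len(new.free_parameters)
        new._check_identification()
        return new

    # ------------------------------------------------------ convenience specs
    @classmethod
    def saturated(cls, variables: list[str], meanstructure: bool = True) -> "ModelSpec":
        cov = [
            (variables[i], variables[j], None)
            for i in range(len(variables))
            for j in range(i, len(variables))
        ]
        return cls([], [], cov, observed_order=list(variables), meanstructure=meanstructure)

    @classmethod
    def independence(cls, variables: list[str], meanstructure: bool = False) -> "ModelSpec":
        cov = [(v, v, None) for v in variables]
        return cls(
            [],
            [],
            cov,
            observed_order=list(variables),
            meanstructure=meanstructure,
            default_exo_cov=False,
        )
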