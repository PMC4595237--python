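"""VS/UVS spectral classification of sw1 opsins and the logistic link to omega.

Avian SWS1 (sw1) cone opsins are violet-sensitive (VS) or
ultraviolet-sensitive (UVS) depending on spectral-tuning residues in the
84-94 region (bovine rhodopsin numbering); the key site is 90, where
cysteine marks UVS and serine VS.  A logistic regression of the binary
class on the species' omega-lineage quantifies how accelerated sw1
evolution tracks the UVS condition: the fitted linear predictor is the
"VS log-odd score" beta0 + beta1 * omega.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .codon_evol import reference_site_map
from .io_formats import SequenceAlignment, TraitTable

logger = logging.getLogger("opsinevol")

__all__ = ["SpectralRuleSet", "LogisticFit", "classify_sws1", "logistic_fit",
           "predict_probability"]


@dataclass(frozen=True)
class SpectralRuleSet:
    """Residue -> spectral class rules at reference-numbered tuning sites.

    The default is the minimal site-90 rule (C90 -> UVS, S90 -> VS);
    additional (site, residue) rules and per-species overrides (which
    always win, e.g. for lineages whose published classification
    contradicts the genomic rule) can be supplied.
    """

    sites: tuple[int, ...] = (86, 90, 93)
    rules: Mapping[tuple[int, str], str] = field(
        default_factory=lambda: {(90, "C"): "UVS", (90, "S"): "VS"})
    overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in list(self.rules.values()) + list(self.overrides.values()):
            if cls not in ("VS", "UVS"):
                raise ValueError(f"class must be VS or UVS, got {cls!r}")


def classify_sws1(alignment: SequenceAlignment, reference_taxon: str,
                  rules: SpectralRuleSet | None = None
                  ) -> tuple[TraitTable, pd.DataFrame]:
    """Call VS (1) or UVS (0) per species from tuning-site residues.

    ``alignment`` is an aligned amino-acid FASTA; ``reference_taxon``
    anchors the site numbering.  Returns the binary trait table (species
    matching no rule are left out) and a per-species report with the
    observed residues at every rule site, the call, and how it was made
    (rule / override / unclassified) — no classification is silent.
    """
    rules = rules or SpectralRuleSet()
    site_map = reference_site_map(alignment, reference_taxon)
    columns = {}
    for site in rules.sites:
        try:
            columns[site] = site_map.column_of(site)
        except KeyError:
            raise ValueError(
                f"rule site {site} is outside the reference sequence") from None

    rows = []
    calls: dict[str, int] = {}
    for taxon in alignment.taxa:
        seq = alignment.sequence(taxon)
        residues = {site: seq[col - 1] for site, col in columns.items()}
        if taxon in rules.overrides:
            call, how = rules.overrides[taxon], "override"
        else:
            call, how = None, "unclassified"
            for site in rules.sites:
                key = (site, residues[site])
                if key in rules.rules:
                    call, how = rules.rules[key], f"rule {key[1]}{site}"
                    break
        if call is not None:
            calls[taxon] = 1 if call == "VS" else 0
        rows.append({"species": taxon, "call": call or "unclassified",
                     "basis": how,
                     **{f"site{site}": res for site, res in residues.items()}})
    report = pd.DataFrame(rows).set_index("species")
    unclassified = (report["call"] == "unclassified").sum()
    if unclassified:
        logger.warning("classify_sws1: %d species matched no rule", unclassified)
    return TraitTable(pd.Series(calls, dtype=int)), report


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression of VS (=1) on omega-lineage."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    z_beta0: float
    z_beta1: float
    p_beta0: float
    p_beta1: float
    n: int
    converged: bool
    separation: bool

    def log_odds(self, omega: float) -> float:
        return self.beta0 + self.beta1 * omega


def logistic_fit(x, y: TraitTable | pd.Series) -> LogisticFit:
    """Fit VS/UVS ~ omega-lineage by IRLS maximum likelihood.

    ``x`` maps species to omega-lineage values; only species present in
    both inputs are used, and at least two of each class are required.
    Complete separation is flagged (coefficients diverge, Wald tests are
    meaningless) rather than reported as a converged fit.
    """
    x = pd.Series(dict(x), dtype=float) if not isinstance(x, pd.Series) else x.astype(float)
    ys = y.data if isinstance(y, TraitTable) else y
    joined = pd.DataFrame({"x": x, "y": ys.astype(float)}).dropna()
    n = len(joined)
    if n < 4:
        raise ValueError("need at least 4 jointly observed species")
    if not np.isfinite(joined["x"]).all():
        raise ValueError("omega values must be finite")
    counts = joined["y"].value_counts()
    if counts.get(0.0, 0) < 2 or counts.get(1.0, 0) < 2:
        # (near-)degenerate response: the MLE is on the boundary
        logger.warning("logistic_fit: <2 species in one class; flagging separation")
        return LogisticFit(beta0=np.nan, beta1=np.nan, se_beta0=np.nan,
                           se_beta1=np.nan, z_beta0=np.nan, z_beta1=np.nan,
                           p_beta0=np.nan, p_beta1=np.nan, n=n,
                           converged=False, separation=True)
    if joined["x"].nunique() == 1:
        # constant predictor: slope 0, intercept = log-odds of the VS fraction
        frac = joined["y"].mean()
        b0 = float(np.log(frac / (1 - frac)))
        se0 = float(1.0 / np.sqrt(n * frac * (1 - frac)))
        from scipy.stats import norm
        return LogisticFit(beta0=b0, beta1=0.0, se_beta0=se0, se_beta1=np.nan,
                           z_beta0=b0 / se0, z_beta1=np.nan,
                           p_beta0=float(2 * norm.sf(abs(b0 / se0))),
                           p_beta1=np.nan, n=n, converged=True,
                           separation=False)

    exog = sm.add_constant(joined["x"].to_numpy())
    model = sm.Logit(joined["y"].to_numpy(), exog)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=False, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:  # PerfectSeparationError and kin
            separation, converged, res = True, False, None
    if res is not None and not separation:
        # diverging coefficients with a perfect fit also mean separation
        fitted = expit(exog @ res.params)
        if np.all(np.abs(fitted - joined["y"].to_numpy()) < 1e-6):
            separation = True
    if separation or res is None:
        logger.warning("logistic_fit: complete separation, no Wald inference")
        return LogisticFit(beta0=np.nan, beta1=np.nan, se_beta0=np.nan,
                           se_beta1=np.nan, z_beta0=np.nan, z_beta1=np.nan,
                           p_beta0=np.nan, p_beta1=np.nan, n=n,
                           converged=False, separation=True)
    b0, b1 = res.params
    se0, se1 = res.bse
    return LogisticFit(beta0=float(b0), beta1=float(b1),
                       se_beta0=float(se0), se_beta1=float(se1),
                       z_beta0=float(b0 / se0), z_beta1=float(b1 / se1),
                       p_beta0=float(res.pvalues[0]), p_beta1=float(res.pvalues[1]),
                       n=n, converged=converged, separation=False)


def predict_probability(fit, omega: float) -> float:
    """P(VS | omega) = inverse-logit(beta0 + beta1 * omega).

    ``fit`` is a :class:`LogisticFit` or a ``(beta0, beta1)`` pair, so
    published coefficients can be evaluated directly.
    """
    if isinstance(fit, LogisticFit):
        b0, b1 = fit.beta0, fit.beta1
    else:
        b0, b1 = fit
    if not (np.isfinite(b0) and np.isfinite(b1) and np.isfinite(omega)):
        raise ValueError("coefficients and omega must be finite")
    return float(expit(b0 + b1 * omega))
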