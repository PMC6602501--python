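"""Complex scoring: raw score, shuffled background, Z score, binder call.

A residue pair's score sums, over the modes in which it touches,
``w(a,b,m) * g(a,b,m,n_m)``; a pair with any steric clash instead
contributes the penalty ``kappa * n_clash`` (positive, destabilising under
the energy convention where favourable scores are negative).  The raw
score S of a complex is the sum over its interacting pairs and the
normalised raw score is S divided by the number of pairs N.

Stability is judged by a Z score against a null in which each interface
residue's amino-acid identity is redrawn from a background composition
while the contact topology, the per-mode atom counts and the clash counts
stay fixed — an operational model of "non-native" interfaces.  Because
lower (more negative) scores are more favourable, Z = (mu - S) / sigma, so
complexes scoring far below their shuffled background get large positive Z
and are called binders when Z >= 1.5 (the calibrated cutoff at 4 Å).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import (
    DEFAULT_CLASH_CUTOFF,
    DEFAULT_THRESHOLD,
    MODES,
    InterfaceSet,
    ResiduePairContact,
    find_contacts,
)
from .errors import DegenerateBackgroundError, NoInterfaceError, ParameterError
from .potential import AA_INDEX, N_AA, Potential
from .structure import AA_ORDER, Structure

DEFAULT_Z_CUTOFF = 1.5
DEFAULT_N_SAMPLES = 10_000
MIN_N_SAMPLES = 100

BINDER = "Binder"
NON_BINDER = "Non-binder"


def z_cutoff_for_threshold(d: float) -> float:
    """Z cutoff tau(d).  Calibrated to 1.5 at 4 Å; the 6 and 8 Å cutoffs
    have not been validated here and default to the same value."""
    return DEFAULT_Z_CUTOFF


@dataclass
class BackgroundDistribution:
    """Moments of the shuffled-interface score distribution."""

    mu: float
    sigma: float
    n_samples: int
    seed: int


@dataclass
class ScoreReport:
    """Full scoring result for a complex or a single chain-pair interface."""

    structure_id: str
    interface: str  # "all" or e.g. "A:B"
    pair_scores: list[tuple[ResiduePairContact, float]]
    S: float
    N: int
    S_norm: float
    mu: float
    sigma: float
    Z: float
    prediction: str
    threshold_d: float
    z_cutoff: float
    per_interface: dict[str, "ScoreReport"] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        d = {
            "structure": self.structure_id,
            "interface": self.interface,
            "n_interacting_pairs": self.N,
            "raw_score": round(self.S, 4),
            "normalized_raw_score": round(self.S_norm, 4),
            "background_mu": round(self.mu, 4),
            "background_sigma": round(self.sigma, 4),
            "z_score": round(self.Z, 4),
            "prediction": self.prediction,
            "threshold_d": self.threshold_d,
            "z_cutoff": self.z_cutoff,
        }
        if self.per_interface:
            d["interfaces"] = {
                k: v.summary_dict() for k, v in sorted(self.per_interface.items())
            }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2) + "\n")


def score_pair(c: ResiduePairContact, p: Potential) -> float:
    """Score one interacting residue pair.

    Clash-free pairs sum mode weights damped by the atomic propensity at
    the observed contact count; clashing pairs are replaced wholesale by
    the positive penalty ``kappa * n_clash``.
    """
    if c.n_clash > 0:
        return p.kappa * c.n_clash
    total = 0.0
    for mode in MODES:
        n = c.count(mode)
        if n >= 1:
            total += p.weight(c.res_i.aa, c.res_j.aa, mode) * p.propensity_factor(
                c.res_i.aa, c.res_j.aa, mode, n
            )
    return total


def raw_score(iface: InterfaceSet, p: Potential) -> tuple[float, int]:
    """Raw score S (sum of pair scores) and pair count N of an interface."""
    if len(iface) == 0:
        raise NoInterfaceError("no interacting residues at this threshold")
    S = sum(score_pair(c, p) for c in iface.pairs)
    return S, len(iface)


def normalize_score(S: float, N: int) -> float:
    """Normalised raw score S / N."""
    if N < 1:
        raise ParameterError("cannot normalise a score over zero pairs")
    return S / N


def _pair_score_tables(
    iface: InterfaceSet, p: Potential
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list]:
    """Vectorisation helper for the background sampler.

    For every clash-free pair the score as a function of the two redrawn
    labels is a fixed (20, 20) table (the contact counts do not change
    under the shuffle); clashing pairs contribute a label-independent
    constant.  Returns per-pair tables, the residue-index pairs they
    couple, and the constant term.
    """
    residues = iface.residues()
    res_pos = {id(r): k for k, r in enumerate(residues)}
    tables, idx_i, idx_j = [], [], []
    const = 0.0
    for c in iface.pairs:
        if c.n_clash > 0:
            const += p.kappa * c.n_clash
            continue
        table = np.zeros((N_AA, N_AA))
        for mode in MODES:
            n = c.count(mode)
            if n >= 1:
                table += p.w[mode] * p.propensity_matrix(mode, n)
        tables.append(table)
        idx_i.append(res_pos[id(c.res_i)])
        idx_j.append(res_pos[id(c.res_j)])
    return (
        np.asarray(tables) if tables else np.zeros((0, N_AA, N_AA)),
        np.asarray(idx_i, dtype=int),
        np.asarray(idx_j, dtype=int),
        const,
        residues,
    )


def background_distribution(
    iface: InterfaceSet,
    p: Potential,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    composition: np.ndarray | dict[str, float] | None = None,
) -> BackgroundDistribution:
    """Score distribution over label-shuffled ("non-native") interfaces.

    Each of the ``n_samples`` pseudo-interfaces redraws every interface
    residue's amino-acid identity independently from ``composition``
    (default: the interface's own residue composition), keeping the
    contact topology and all per-mode atom and clash counts fixed, and is
    scored with the same potential.  Returns the sample mean and standard
    deviation; fully reproducible from ``seed``.
    """
    if n_samples < MIN_N_SAMPLES:
        raise ParameterError(f"n_samples must be >= {MIN_N_SAMPLES}")
    if len(iface) == 0:
        raise NoInterfaceError("no interacting residues at this threshold")

    tables, idx_i, idx_j, const, residues = _pair_score_tables(iface, p)

    if composition is None:
        comp = np.zeros(N_AA)
        for r in residues:
            comp[AA_INDEX[r.aa]] += 1
    elif isinstance(composition, dict):
        comp = np.zeros(N_AA)
        for aa, v in composition.items():
            comp[AA_INDEX[aa]] = v
    else:
        comp = np.asarray(composition, dtype=float)
        if comp.shape != (N_AA,):
            raise ParameterError(f"composition must have {N_AA} entries")
    if comp.sum() <= 0:
        raise ParameterError("background composition is empty")
    comp = comp / comp.sum()

    rng = np.random.default_rng(seed)
    labels = rng.choice(N_AA, size=(n_samples, len(residues)), p=comp)
    scores = np.full(n_samples, const)
    for k in range(tables.shape[0]):
        scores += tables[k][labels[:, idx_i[k]], labels[:, idx_j[k]]]
    mu = float(scores.mean())
    sigma = float(scores.std())
    if sigma < 1e-12 * max(1.0, abs(mu)):
        sigma = 0.0  # constant background up to float summation noise
    return BackgroundDistribution(
        mu=mu, sigma=sigma, n_samples=n_samples, seed=seed
    )


def z_score(S: float, bg: BackgroundDistribution) -> float:
    """Z = (mu - S) / sigma: scores below background give positive Z."""
    if bg.sigma <= 0:
        raise DegenerateBackgroundError(
            "background distribution has zero variance (sigma = 0); "
            "Z score is undefined — use a richer background composition"
        )
    return (bg.mu - S) / bg.sigma


def classify(Z: float, d: float = DEFAULT_THRESHOLD, z_cutoff: float | None = None) -> str:
    """Binder iff Z >= tau(d); the boundary itself counts as Binder."""
    tau = z_cutoff_for_threshold(d) if z_cutoff is None else z_cutoff
    return BINDER if Z >= tau else NON_BINDER


def _report_for(
    structure_id: str,
    interface: str,
    iface: InterfaceSet,
    p: Potential,
    d: float,
    n_samples: int,
    seed: int,
    z_cutoff: float,
    composition,
) -> ScoreReport:
    pair_scores = [(c, score_pair(c, p)) for c in iface.pairs]
    S = sum(v for _, v in pair_scores)
    N = len(iface)
    bg = background_distribution(
        iface, p, n_samples=n_samples, seed=seed, composition=composition
    )
    Z = z_score(S, bg)
    return ScoreReport(
        structure_id=structure_id,
        interface=interface,
        pair_scores=pair_scores,
        S=S,
        N=N,
        S_norm=normalize_score(S, N),
        mu=bg.mu,
        sigma=bg.sigma,
        Z=Z,
        prediction=classify(Z, d, z_cutoff),
        threshold_d=d,
        z_cutoff=z_cutoff,
    )


def score_complex(
    s: Structure,
    p: Potential,
    d: float = DEFAULT_THRESHOLD,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
    z_cutoff: float | None = None,
    composition: np.ndarray | dict[str, float] | None = None,
) -> ScoreReport:
    """Score a whole complex plus every chain-pair interface separately.

    Multimers are scored as a whole — no receptor/ligand split is needed —
    and each chain-pair interface additionally gets its own sub-report
    (its own background and Z).  Raises :class:`NoInterfaceError` when no
    chains touch at the threshold.
    """
    tau = z_cutoff_for_threshold(d) if z_cutoff is None else z_cutoff
    iface = find_contacts(s, d=d, clash_cutoff=clash_cutoff)
    if len(iface) == 0:
        raise NoInterfaceError(
            f"structure {s.id!r} has no interacting residues at {d} Å"
        )
    report = _report_for(
        s.id, "all", iface, p, d, n_samples, seed, tau, composition
    )
    for k, chain_pair in enumerate(iface.interfaces):
        sub = iface.subset(chain_pair)
        report.per_interface[":".join(chain_pair)] = _report_for(
            s.id, ":".join(chain_pair), sub, p, d, n_samples,
            seed + 1 + k, tau, composition,
        )
    return report


def score_file_frame(report: ScoreReport) -> pd.DataFrame:
    """The parameters-and-scores table (one row per interface + the whole)."""
    rows = []
    for name, rep in [("all", report)] + sorted(report.per_interface.items()):
        rows.append(
            {
                "interface": name,
                "threshold_d": rep.threshold_d,
                "z_cutoff": rep.z_cutoff,
                "n_interacting_pairs": rep.N,
                "raw_score": round(rep.S, 4),
                "normalized_raw_score": round(rep.S_norm, 4),
                "z_score": round(rep.Z, 4),
                "prediction": rep.prediction,
            }
        )
    return pd.DataFrame(rows)


def pair_scores_frame(report: ScoreReport) -> pd.DataFrame:
    """Per-pair score listing (the interacting-interface-residues table)."""
    rows = [
        {
            "chain_i": c.res_i.chain_id,
            "resnum_i": f"{c.res_i.seq_id}{c.res_i.icode}",
            "resname_i": c.res_i.aa3,
            "chain_j": c.res_j.chain_id,
            "resnum_j": f"{c.res_j.seq_id}{c.res_j.icode}",
            "resname_j": c.res_j.aa3,
            "d_min": round(c.d_min, 3),
            "n_mm": c.n_mm,
            "n_ms": c.n_ms,
            "n_ss": c.n_ss,
            "n_clash": c.n_clash,
            "score": round(v, 4),
        }
        for c, v in report.pair_scores
    ]
    return pd.DataFrame(rows)
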