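"""Derivation and I/O of the knowledge-based pair potential.

The potential has three parts:

* three symmetric 20x20 matrices of residue-pair weights, one per
  interaction mode (MM, MS, SS).  Each weight is the negative log ratio of
  the observed inter-chain pair frequency in a training corpus to the
  frequency expected from interface composition alone,
  ``w(a,b,m) = -ln(f_obs(a,b,m) / f_exp(a,b))`` with
  ``f_exp(a,b) = p_a * p_b * (2 - delta_ab)``.  Pairs enriched at
  interfaces (favourable energetics) score negative;

* atomic-contact propensity tables ``g(a,b,m,n)`` — the empirical
  distribution of how many atom-atom contacts mediate a pair interaction,
  normalised so the modal count maps to 1.0.  Pairs interacting through
  their typical number of atoms keep their full weight; atypical counts
  are damped toward a floor;

* a clash penalty ``kappa`` applied per clashing atom pair.

All parts serialise to a plain-text directory so users can supply custom
matrices.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contacts import DEFAULT_CLASH_CUTOFF, DEFAULT_THRESHOLD, MODES, find_contacts
from .errors import ParameterError, PotentialFormatError
from .structure import AA_ORDER, Structure

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
N_AA = len(AA_ORDER)

#: Atom-count bins: raw 1..10, with 11+ pooled into the last bin.
MAX_BIN = 11
DEFAULT_G_FLOOR = 0.1
DEFAULT_KAPPA = 1.0
DEFAULT_ALPHA = 1.0

_MATRIX_FILES = {m: f"matrix_{m}.txt" for m in MODES}
_PROPENSITY_FILE = "propensities.tsv"
_METADATA_FILE = "metadata.txt"


def _bin_count(n: int) -> int:
    return min(int(n), MAX_BIN)


@dataclass
class Potential:
    """Scoring parameters: mode matrices, propensity tables, clash penalty.

    ``w`` maps mode -> symmetric (20, 20) array indexed by :data:`AA_ORDER`.
    ``g`` maps (mode, a, b) with a <= b -> dict of atom-count bin -> factor;
    an empty ``g`` means the propensity factor is 1 everywhere.
    """

    w: dict[str, np.ndarray]
    g: dict[tuple[str, str, str], dict[int, float]] = field(default_factory=dict)
    kappa: float = DEFAULT_KAPPA
    threshold_d: float = DEFAULT_THRESHOLD
    g_floor: float = DEFAULT_G_FLOOR
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in MODES:
            if m not in self.w:
                raise ParameterError(f"missing matrix for mode {m}")
            mat = np.asarray(self.w[m], dtype=float)
            if mat.shape != (N_AA, N_AA):
                raise PotentialFormatError(
                    f"mode {m}: matrix must be {N_AA}x{N_AA}, got {mat.shape}"
                )
            if not np.allclose(mat, mat.T, atol=1e-4):
                raise PotentialFormatError(f"mode {m}: matrix is not symmetric")
            self.w[m] = mat

    def weight(self, a: str, b: str, mode: str) -> float:
        return float(self.w[mode][AA_INDEX[a], AA_INDEX[b]])

    def propensity_factor(self, a: str, b: str, mode: str, n: int) -> float:
        """g(a, b, mode, n): 1.0 at the modal atom count, floor if unseen."""
        if n < 1:
            raise ParameterError("atom-contact count must be >= 1")
        if not self.g:
            return 1.0
        key = (mode, *sorted((a, b)))
        table = self.g.get(key)
        if table is None:
            return 1.0
        return table.get(_bin_count(n), self.g_floor)

    def propensity_matrix(self, mode: str, n: int) -> np.ndarray:
        """(20, 20) array of g(.,.,mode,n) — used to vectorise scoring."""
        out = np.ones((N_AA, N_AA))
        if not self.g:
            return out
        nb = _bin_count(n)
        for i, a in enumerate(AA_ORDER):
            for j in range(i, N_AA):
                b = AA_ORDER[j]
                table = self.g.get((mode, a, b))
                if table is not None:
                    out[i, j] = out[j, i] = table.get(nb, self.g_floor)
        return out


def uniform_potential(value: float = 0.0, **kwargs) -> Potential:
    """A potential with every pair weight equal to ``value`` and g = 1."""
    return Potential(w={m: np.full((N_AA, N_AA), value) for m in MODES}, **kwargs)


@dataclass
class TrainingCorpus:
    """A set of training complexes plus a per-structure manifest.

    ``generation``, when present, records the model that generated a
    synthetic corpus (pair-type frequencies, composition, seed) and serves
    as the oracle for parameter-recovery tests.
    """

    structures: list[Structure]
    manifest: list[dict] = field(default_factory=list)
    generation: dict | None = None

    def __len__(self) -> int:
        return len(self.structures)


def _observed_frequencies(
    counts: np.ndarray, alpha: float
) -> np.ndarray:
    """Smoothed pair frequencies over the 210 unordered cells of one mode.

    Returns a symmetric (20, 20) array whose upper triangle (incl. diagonal)
    sums to 1.
    """
    iu = np.triu_indices(N_AA)
    smoothed = counts[iu] + alpha
    freq = np.zeros((N_AA, N_AA))
    freq[iu] = smoothed / smoothed.sum()
    return freq + np.triu(freq, 1).T


def derive_potential(
    corpus: TrainingCorpus,
    d: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
    kappa: float = DEFAULT_KAPPA,
    g_floor: float = DEFAULT_G_FLOOR,
) -> Potential:
    """Derive the pair potential from a corpus of complexes.

    For each mode, every interacting residue pair with at least one contact
    in that mode contributes one count.  Observed frequencies are smoothed
    with pseudocount ``alpha``; expected frequencies come from the corpus
    interface residue composition (each interface residue counted once,
    smoothed with the same alpha) via ``p_a * p_b * (2 - delta_ab)``.
    Propensity tables are the per-(a, b, mode) empirical distributions of
    atom-contact counts normalised to the modal count.
    """
    if len(corpus) == 0:
        raise ParameterError("training corpus is empty")
    if alpha <= 0:
        raise ParameterError("pseudocount alpha must be > 0")

    pair_counts = {m: np.zeros((N_AA, N_AA)) for m in MODES}
    n_counts: dict[tuple[str, str, str], dict[int, int]] = {}
    comp = np.zeros(N_AA)

    for s in corpus.structures:
        iface = find_contacts(s, d=d, clash_cutoff=clash_cutoff)
        for res in iface.residues():
            comp[AA_INDEX[res.aa]] += 1
        for p in iface.pairs:
            i, j = AA_INDEX[p.res_i.aa], AA_INDEX[p.res_j.aa]
            key_ab = tuple(sorted((p.res_i.aa, p.res_j.aa)))
            for mode in MODES:
                n = p.count(mode)
                if n >= 1:
                    pair_counts[mode][i, j] += 1
                    if i != j:
                        pair_counts[mode][j, i] += 1
                    tbl = n_counts.setdefault((mode, *key_ab), {})
                    nb = _bin_count(n)
                    tbl[nb] = tbl.get(nb, 0) + 1

    # expected frequencies from smoothed interface composition
    p_comp = (comp + alpha) / (comp.sum() + N_AA * alpha)
    f_exp = np.outer(p_comp, p_comp) * (2.0 - np.eye(N_AA))

    w: dict[str, np.ndarray] = {}
    for mode in MODES:
        # pair_counts is symmetric with off-diagonal double counted; the
        # upper triangle holds one count per unordered pair occurrence
        if pair_counts[mode].sum() == 0:
            warnings.warn(
                f"mode {mode}: no contacts in corpus; matrix set to zero",
                stacklevel=2,
            )
            w[mode] = np.zeros((N_AA, N_AA))
            continue
        f_obs = _observed_frequencies(np.triu(pair_counts[mode]), alpha)
        w[mode] = -np.log(f_obs / f_exp)

    g: dict[tuple[str, str, str], dict[int, float]] = {}
    for key, tbl in n_counts.items():
        peak = max(tbl.values())
        g[key] = {n: c / peak for n, c in tbl.items()}

    manifest_digest = hashlib.sha256(
        "|".join(s.id for s in corpus.structures).encode()
    ).hexdigest()[:16]
    return Potential(
        w=w,
        g=g,
        kappa=kappa,
        threshold_d=d,
        g_floor=g_floor,
        metadata={
            "threshold_d": repr(float(d)),
            "alpha": repr(float(alpha)),
            "kappa": repr(float(kappa)),
            "g_floor": repr(float(g_floor)),
            "corpus_hash": manifest_digest,
            "n_structures": str(len(corpus)),
        },
    )


def write_potential(p: Potential, directory: str | Path) -> None:
    """Serialise a potential to plain-text files in ``directory``.

    One ``matrix_<MODE>.txt`` per mode (tab-separated, one-letter header row
    and column, 4 decimal places), a propensity table and a metadata file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for mode in MODES:
        lines = ["\t" + "\t".join(AA_ORDER)]
        for i, aa in enumerate(AA_ORDER):
            row = "\t".join(f"{p.w[mode][i, j]:.4f}" for j in range(N_AA))
            lines.append(f"{aa}\t{row}")
        (directory / _MATRIX_FILES[mode]).write_text("\n".join(lines) + "\n")

    with open(directory / _PROPENSITY_FILE, "w") as fh:
        fh.write("a\tb\tmode\tn\tfactor\n")
        for (mode, a, b), tbl in sorted(p.g.items()):
            for n in sorted(tbl):
                fh.write(f"{a}\t{b}\t{mode}\t{n}\t{tbl[n]:.6f}\n")

    meta = dict(p.metadata)
    meta.update(
        threshold_d=repr(float(p.threshold_d)),
        kappa=repr(float(p.kappa)),
        g_floor=repr(float(p.g_floor)),
    )
    (directory / _METADATA_FILE).write_text(
        "".join(f"{k}={v}\n" for k, v in sorted(meta.items()))
    )


def _read_matrix(path: Path) -> np.ndarray:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    header = [h for h in header if h.strip()]
    if header != list(AA_ORDER):
        raise PotentialFormatError(
            f"{path.name}: header must list the 20 amino acids {AA_ORDER}"
        )
    if len(lines) - 1 != N_AA:
        raise PotentialFormatError(
            f"{path.name}: expected {N_AA} rows, found {len(lines) - 1}"
        )
    mat = np.zeros((N_AA, N_AA))
    for i, ln in enumerate(lines[1:]):
        parts = ln.split("\t")
        if parts[0] != AA_ORDER[i]:
            raise PotentialFormatError(
                f"{path.name}: row {i + 1} labelled {parts[0]!r}, "
                f"expected {AA_ORDER[i]!r}"
            )
        if len(parts) - 1 != N_AA:
            raise PotentialFormatError(
                f"{path.name}: row {parts[0]} has {len(parts) - 1} columns, "
                f"expected {N_AA}"
            )
        try:
            mat[i] = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise PotentialFormatError(
                f"{path.name}: non-numeric cell in row {parts[0]}"
            ) from exc
    if not np.allclose(mat, mat.T, atol=1e-4):
        raise PotentialFormatError(f"{path.name}: matrix is not symmetric")
    return mat


def read_potential(directory: str | Path) -> Potential:
    """Load a potential from a plain-text directory written by
    :func:`write_potential` (or hand-built to the same format).

    Matrix files are required; a missing propensity file means g = 1
    everywhere and missing metadata falls back to defaults.
    """
    directory = Path(directory)
    w = {}
    for mode in MODES:
        path = directory / _MATRIX_FILES[mode]
        if not path.exists():
            raise PotentialFormatError(f"missing matrix file {path}")
        w[mode] = _read_matrix(path)

    metadata: dict[str, str] = {}
    meta_path = directory / _METADATA_FILE
    if meta_path.exists():
        for ln in meta_path.read_text().splitlines():
            if "=" in ln:
                k, v = ln.split("=", 1)
                metadata[k.strip()] = v.strip()
    kappa = float(metadata.get("kappa", DEFAULT_KAPPA))
    threshold_d = float(metadata.get("threshold_d", DEFAULT_THRESHOLD))
    g_floor = float(metadata.get("g_floor", DEFAULT_G_FLOOR))

    g: dict[tuple[str, str, str], dict[int, float]] = {}
    prop_path = directory / _PROPENSITY_FILE
    if prop_path.exists():
        lines = prop_path.read_text().splitlines()
        for ln in lines[1:]:
            if not ln.strip():
                continue
            a, b, mode, n, factor = ln.split("\t")
            if mode not in MODES or a not in AA_INDEX or b not in AA_INDEX:
                raise PotentialFormatError(
                    f"{prop_path.name}: bad propensity row {ln!r}"
                )
            g.setdefault((mode, *sorted((a, b))), {})[int(n)] = float(factor)

    return Potential(
        w=w, g=g, kappa=kappa, threshold_d=threshold_d,
        g_floor=g_floor, metadata=metadata,
    )
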