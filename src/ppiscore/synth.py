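"""Synthetic protein-complex fixtures with controlled interfaces.

Real training sets and benchmark decoys are large downloads; every other
module in this package is instead exercised on generated complexes whose
interface properties are known by construction:

* chains are idealised extended strands ("ladders") whose residues sit on
  rungs 6 Å apart; each residue has a four-atom backbone (N, CA, C, O) in
  its chain's plane plus 1-3 side-chain pseudo-atoms extending
  perpendicular to it, the tip always 3 Å from the plane;

* in the default ``ss`` geometry adjacent chains face each other
  side-chain-to-side-chain, so the closest atom pair of each rung is the
  two tips, exactly ``inter_chain_gap`` apart; at the 4 Å threshold every
  rung whose two residues both have side chains contributes exactly one
  side-side contact.  The ``mixed`` geometry puts backbone planes
  ``inter_chain_gap`` apart with side chains swept aside, producing
  main-main and main-side contacts; the ``clique`` layout drops all
  chains onto a small circle so every chain pair touches;

* rung residue types are drawn from an unordered pair-type distribution
  proportional to ``composition x composition x (2 - delta)`` optionally
  multiplied by planted fold-enrichments, so derived potentials can be
  checked against the closed-form generating model;

* steric clashes are planted as dedicated atom pairs 0.8 Å apart, one
  per requested clash, placed so they perturb nothing else.

Glycine has no side-chain heavy atoms, so ``ss``-geometry fixtures default
to a glycine-free composition; a glycine rung would simply fail to touch.

All randomness flows through one ``numpy`` generator seeded from the spec;
identical specs produce byte-identical PDB output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import ParameterError
from .potential import TrainingCorpus
from .structure import AA_ORDER, ONE_TO_THREE, Structure, read_structure

RUNG_SPACING = 6.0  # Å between rungs along the chain axis
TIP_EXT = 3.0  # Å from backbone plane to side-chain tip

#: side-chain pseudo-atom count per residue type (0 for glycine).
_N_SC = {aa: 2 for aa in AA_ORDER}
_N_SC.update({"G": 0, "A": 1, "S": 1, "C": 1, "T": 1, "V": 1,
              "F": 3, "R": 3, "W": 3, "Y": 3, "K": 3})
_SC_NAMES = ("CB", "CG", "CD")

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

AA_NO_GLY = AA_ORDER.replace("G", "")


def _as_composition(composition, alphabet: str) -> dict[str, float]:
    if composition is None:
        return {aa: 1.0 / len(alphabet) for aa in alphabet}
    if isinstance(composition, dict):
        comp = dict(composition)
    else:
        comp = {aa: float(v) for aa, v in zip(AA_ORDER, composition)}
    comp = {aa: v for aa, v in comp.items() if v > 0}
    total = sum(comp.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        comp = {aa: v / total for aa, v in comp.items()}
    return comp


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic complex."""

    n_chains: int = 2
    chain_lengths: list[int] | None = None  # default: 8 residues each
    composition: dict[str, float] | None = None
    inter_chain_gap: float = 3.5
    planted_enrichments: list[tuple[str, str, str, float]] = field(
        default_factory=list
    )  # (aa, aa, mode, fold)
    planted_clashes: int = 0
    seed: int = 0
    geometry: str = "ss"  # "ss" | "mixed"
    layout: str = "stack"  # "stack" | "clique"
    jitter: float = 0.0  # uniform coordinate noise half-width, Å

    def lengths(self) -> list[int]:
        if self.chain_lengths is None:
            return [8] * self.n_chains
        if len(self.chain_lengths) != self.n_chains:
            raise ParameterError("chain_lengths must match n_chains")
        return list(self.chain_lengths)

    def validate(self) -> None:
        if self.n_chains < 1:
            raise ParameterError("need at least one chain")
        if self.n_chains > len(_CHAIN_IDS):
            raise ParameterError(f"at most {len(_CHAIN_IDS)} chains supported")
        if self.geometry not in ("ss", "mixed"):
            raise ParameterError(f"unknown geometry {self.geometry!r}")
        if self.layout not in ("stack", "clique"):
            raise ParameterError(f"unknown layout {self.layout!r}")
        if self.inter_chain_gap <= 0 and self.planted_clashes == 0:
            raise ParameterError(
                "non-positive inter_chain_gap without planted clashes "
                "is an infeasible geometry"
            )
        if self.geometry == "ss" and self.inter_chain_gap < 3.2:
            raise ParameterError(
                "ss geometry needs inter_chain_gap >= 3.2 Å to keep the "
                "tip-tip pair the unique closest contact"
            )
        if self.planted_clashes and (self.n_chains != 2 or self.layout != "stack"):
            raise ParameterError("planted clashes require a stacked dimer")
        for a, b, mode, fold in self.planted_enrichments:
            if a not in AA_ORDER or b not in AA_ORDER or fold <= 0:
                raise ParameterError(f"bad enrichment ({a},{b},{mode},{fold})")


@dataclass
class Fixture:
    """A generated complex plus everything the generator planted."""

    structure: Structure
    pdb_text: str
    spec: FixtureSpec
    rung_pairs: list[tuple[str, str]]  # residue-type pairs actually in contact
    n_clashes_planted: int
    pair_probs: dict[tuple[str, str], float]  # generating unordered pair freqs


def _pair_distribution(
    comp: dict[str, float],
    enrichments: list[tuple[str, str, str, float]],
    active_modes: tuple[str, ...],
) -> dict[tuple[str, str], float]:
    """Unordered pair-type probabilities with planted fold enrichments.

    Without enrichments this is the composition outer product with the
    ``(2 - delta)`` symmetry factor.  A fold enrichment means "this
    pair's frequency is fold times the frequency expected from the
    realised residue composition", so the observed/expected ratio matrix
    is planted directly: enriched cells are fixed at their fold and all
    other cells carry a multiplicative compensation ``s_a * s_b`` fitted
    (Sinkhorn-style) so that every row of ratios averages to one under
    the composition.  The resulting joint ``q(a,b) = comp_a * comp_b *
    ratio(a,b) * (2 - delta)`` then has residue marginals exactly equal
    to the composition while each planted pair sits at exactly its fold —
    which is what makes the derived ``-ln(fold)`` weight recoverable.
    """
    aas = sorted(comp)
    folds: dict[tuple[str, str], float] = {}
    for a, b, mode, fold in enrichments:
        if mode in active_modes:
            key = tuple(sorted((a, b)))
            folds[key] = folds.get(key, 1.0) * fold

    def planted(a: str, b: str) -> float | None:
        return folds.get((a, b) if a <= b else (b, a))

    s = {a: 1.0 for a in aas}
    if folds:
        for _ in range(500):
            delta = 0.0
            for a in aas:
                rhs = 1.0
                denom = 0.0
                for b in aas:
                    f = planted(a, b)
                    if f is None:
                        denom += s[b] * comp[b]
                    else:
                        rhs -= f * comp[b]
                if rhs <= 0 or denom <= 0:
                    raise ParameterError(
                        "planted enrichments are infeasible: folds are too "
                        "large for the composition to compensate"
                    )
                new = rhs / denom
                delta = max(delta, abs(new - s[a]))
                s[a] = new
            if delta < 1e-13:
                break

    probs: dict[tuple[str, str], float] = {}
    for i, a in enumerate(aas):
        for b in aas[i:]:
            ratio = planted(a, b)
            if ratio is None:
                ratio = s[a] * s[b]
            sym = 1.0 if a == b else 2.0
            probs[(a, b)] = comp[a] * comp[b] * sym * ratio
    total = sum(probs.values())  # 1 up to float error
    return {k: v / total for k, v in probs.items()}


def _tip_direction(chain: int, rung: int, n_chains: int) -> int:
    """+1 = side chain toward the next chain, -1 = toward the previous.

    Middle chains alternate per rung so every adjacent chain pair shares
    rungs where the two side chains face each other.
    """
    if chain == 0:
        return +1
    if chain == n_chains - 1:
        return -1
    return +1 if (rung + chain) % 2 == 1 else -1


def _residue_atoms(
    aa: str, base: np.ndarray, sc_axis: np.ndarray
) -> list[tuple[str, np.ndarray]]:
    """Backbone quad in the plane through ``base`` plus side-chain
    pseudo-atoms along ``sc_axis`` with the tip at ``TIP_EXT``."""
    atoms = [
        ("N", base + np.array([-1.2, 0.9, 0.0])),
        ("CA", base.copy()),
        ("C", base + np.array([1.2, 0.9, 0.0])),
        ("O", base + np.array([1.6, 2.0, 0.0])),
    ]
    k = _N_SC[aa]
    if k:
        exts = {1: [TIP_EXT], 2: [TIP_EXT / 2, TIP_EXT], 3: [1.0, 2.0, TIP_EXT]}[k]
        for name, ext in zip(_SC_NAMES, exts):
            atoms.append((name, base + ext * sc_axis))
    return atoms


def _build_pdb(
    chains: list[tuple[str, list[tuple[str, list[tuple[str, np.ndarray]]]]]],
    seed: int,
) -> str:
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    for cid, residues in chains:
        chain = gemmi.Chain(cid)
        for num, (aa, atoms) in enumerate(residues, start=1):
            res = gemmi.Residue()
            res.name = ONE_TO_THREE[aa]
            res.seqid = gemmi.SeqId(num, " ")
            for name, pos in atoms:
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*pos)
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    pdb = st.make_pdb_string()
    return f"REMARK 300 SYNTHETIC FIXTURE SEED {seed}\n" + pdb


def make_complex(spec: FixtureSpec) -> Fixture:
    """Build one synthetic complex from its spec.

    In the stacked layouts the closest inter-chain atom distance equals
    ``spec.inter_chain_gap`` (exactly at ``jitter = 0``) for every
    adjacent chain pair with at least one facing side-chain rung.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lengths = spec.lengths()
    alphabet = AA_NO_GLY if spec.geometry == "ss" else AA_ORDER
    comp = _as_composition(spec.composition, alphabet)
    active = ("SS",) if spec.geometry == "ss" else ("MM", "MS")
    pair_probs = _pair_distribution(comp, spec.planted_enrichments, active)
    pair_keys = list(pair_probs)
    pair_p = np.array([pair_probs[k] for k in pair_keys])
    comp_keys = sorted(comp)
    comp_p = np.array([comp[a] for a in comp_keys])

    if spec.geometry == "ss":
        z_step = spec.inter_chain_gap + 2 * TIP_EXT
    else:
        z_step = spec.inter_chain_gap

    # assign residue types: facing rungs draw a pair type jointly,
    # unpartnered residues draw from the composition
    types: list[list[str]] = [[None] * n for n in lengths]
    rung_pairs: list[tuple[str, str]] = []
    if spec.layout == "stack" and spec.n_chains >= 2:
        for c in range(spec.n_chains - 1):
            n_shared = min(lengths[c], lengths[c + 1])
            for r in range(n_shared):
                if (
                    _tip_direction(c, r, spec.n_chains) == +1
                    and _tip_direction(c + 1, r, spec.n_chains) == -1
                ) or spec.geometry == "mixed":
                    if types[c][r] is not None or types[c + 1][r] is not None:
                        continue
                    a, b = pair_keys[rng.choice(len(pair_keys), p=pair_p)]
                    if rng.random() < 0.5:
                        a, b = b, a
                    types[c][r], types[c + 1][r] = a, b
                    rung_pairs.append(tuple(sorted((a, b))))
    for c in range(spec.n_chains):
        for r in range(lengths[c]):
            if types[c][r] is None:
                types[c][r] = comp_keys[rng.choice(len(comp_keys), p=comp_p)]

    # geometry
    chains = []
    for c in range(spec.n_chains):
        cid = _CHAIN_IDS[c]
        residues = []
        if spec.layout == "clique":
            angle = 2 * np.pi * c / spec.n_chains
            origin = 1.9 * np.array([np.cos(angle), np.sin(angle), 0.0])
        else:
            origin = np.array([0.0, 0.0, c * z_step])
        for r in range(lengths[c]):
            base = origin + np.array([r * RUNG_SPACING, 0.0, 0.0])
            if spec.geometry == "ss" and spec.layout == "stack":
                sc_axis = np.array(
                    [0.0, 0.0, float(_tip_direction(c, r, spec.n_chains))]
                )
            else:
                # side chains swept into the plane, alternating sides
                sc_axis = np.array([0.0, 1.0 if c % 2 == 0 else -1.0, 0.0])
            residues.append((types[c][r], _residue_atoms(types[c][r], base, sc_axis)))
        chains.append((cid, residues))

    # planted clashes: dedicated atom pairs 0.8 Å apart between rungs
    n_clash = spec.planted_clashes
    if n_clash:
        if n_clash > lengths[0]:
            raise ParameterError("more planted clashes than rungs")
        z_mid = z_step / 2.0
        for r in range(n_clash):
            x = r * RUNG_SPACING + RUNG_SPACING / 2.0
            chains[0][1][r][1].append(("CX", np.array([x, 3.0, z_mid - 0.4])))
            chains[1][1][r][1].append(("CX", np.array([x, 3.0, z_mid + 0.4])))
            rp = tuple(sorted((types[0][r], types[1][r])))
            if rp not in rung_pairs:
                rung_pairs.append(rp)

    if spec.jitter > 0:
        for _, residues in chains:
            for _, atoms in residues:
                for i, (name, pos) in enumerate(atoms):
                    atoms[i] = (
                        name,
                        pos + rng.uniform(-spec.jitter, spec.jitter, size=3),
                    )

    pdb_text = _build_pdb(chains, spec.seed)
    structure = read_structure(pdb_text, structure_id=f"synth-{spec.seed}")
    return Fixture(
        structure=structure,
        pdb_text=pdb_text,
        spec=spec,
        rung_pairs=rung_pairs,
        n_clashes_planted=n_clash,
        pair_probs=pair_probs,
    )


def write_fixture(fix: Fixture, path: str | Path) -> None:
    Path(path).write_text(fix.pdb_text)


def make_corpus(
    spec: FixtureSpec,
    n_complexes: int,
    seed: int = 0,
) -> TrainingCorpus:
    """Generate a training corpus of complexes sharing one fixture spec.

    Complex ``i`` uses seed ``seed + i``; the corpus manifest records each
    structure and the ``generation`` block records the pair-type
    distribution that generated the rungs — the oracle for potential
    recovery tests.
    """
    if n_complexes < 1:
        raise ParameterError("n_complexes must be >= 1")
    structures, manifest = [], []
    realized: dict[tuple[str, str], int] = {}
    pair_probs: dict[tuple[str, str], float] = {}
    for i in range(n_complexes):
        sub = FixtureSpec(**{**spec.__dict__, "seed": seed + i})
        fix = make_complex(sub)
        structures.append(fix.structure)
        pair_probs = fix.pair_probs
        for key in fix.rung_pairs:
            realized[key] = realized.get(key, 0) + 1
        manifest.append(
            {
                "id": fix.structure.id,
                "chains": fix.structure.chain_ids,
                "seed": sub.seed,
                "n_rung_pairs": len(fix.rung_pairs),
            }
        )
    generation = {
        "pair_probs": {f"{a}{b}": p for (a, b), p in sorted(pair_probs.items())},
        "realized_counts": {f"{a}{b}": c for (a, b), c in sorted(realized.items())},
        "geometry": spec.geometry,
        "seed": seed,
        "n_complexes": n_complexes,
    }
    return TrainingCorpus(structures=structures, manifest=manifest,
                          generation=generation)


def write_corpus(corpus: TrainingCorpus, directory: str | Path,
                 fixtures: list[Fixture] | None = None) -> None:
    """Write a corpus manifest (and optionally its PDB files) to disk."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {"manifest": corpus.manifest, "generation": corpus.generation}
    (directory / "manifest.json").write_text(json.dumps(payload, indent=2) + "\n")
    if fixtures:
        for fix in fixtures:
            write_fixture(fix, directory / f"{fix.structure.id}.pdb")
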