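"""Distance and hydrogen-bond statistics over conformational ensembles.

Generalizes the D390-K452 / D390-K455 salt-bridge analysis: for every model
of an ensemble (one PDB file per model), the minimum distance over the cross
pairs of named side-chain atoms is computed, classified against a
distance-only hydrogen-bond criterion (cutoff 3.5 A with an 0.5 A acceptance
margin), and summarized as a bonded fraction plus the distribution of
non-bonded distances. Distributions from two ensembles are compared with a
Mann-Whitney U test.

No donor-acceptor angles are evaluated: the criterion is purely a
heavy-atom distance threshold applied to static models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from glob import glob
from pathlib import Path

import numpy as np
from scipy.stats import mannwhitneyu

__all__ = [
    "AtomKey",
    "Ensemble",
    "ResiduePairSpec",
    "HBondPolicy",
    "HBondSummary",
    "MWUResult",
    "load_ensemble",
    "pair_distance",
    "classify_hbond",
    "hbond_summary",
    "mann_whitney_u",
    "parse_pair_spec",
]

AtomKey = tuple[str, int, str, str]  # (chain, residue number, residue name, atom name)


@dataclass
class Model:
    """Atom coordinates of one conformation, keyed by (chain, resid, resname, atom)."""

    source: str
    atoms: dict[AtomKey, np.ndarray]

    def find(self, chain: str, res_id: int, atom_name: str) -> np.ndarray | None:
        """Coordinate lookup ignoring the residue-name component."""
        for (c, r, _rn, a), xyz in self.atoms.items():
            if c == chain and r == res_id and a == atom_name:
                return xyz
        return None


@dataclass
class Ensemble:
    """Ordered list of models plus any per-model load problems."""

    models: list[Model]
    problems: dict[str, str] = field(default_factory=dict)

    @property
    def n_models(self) -> int:
        return len(self.models)


@dataclass
class ResiduePairSpec:
    """Atom groups on each side of a residue pair; distance = min over cross pairs."""

    chain_a: str
    res_a: int
    atoms_a: tuple[str, ...]
    chain_b: str
    res_b: int
    atoms_b: tuple[str, ...]
    reduction: str = "min"  # or "mean"

    def __post_init__(self) -> None:
        if not self.atoms_a or not self.atoms_b:
            raise ValueError("each side needs at least one atom name")
        if self.reduction not in ("min", "mean"):
            raise ValueError("reduction must be 'min' or 'mean'")

    @property
    def name(self) -> str:
        return (f"{self.chain_a}:{self.res_a}:{','.join(self.atoms_a)}"
                f"-{self.chain_b}:{self.res_b}:{','.join(self.atoms_b)}")


def parse_pair_spec(text: str) -> ResiduePairSpec:
    """Parse the compact form ``A:390:OD1,OD2-A:452:NZ``."""
    try:
        side_a, side_b = text.split("-")
        ca, ra, aa = side_a.split(":")
        cb, rb, ab = side_b.split(":")
    except ValueError as err:
        raise ValueError(
            f"malformed pair spec {text!r}; expected CHAIN:RES:ATOMS-CHAIN:RES:ATOMS"
        ) from err
    return ResiduePairSpec(
        chain_a=ca, res_a=int(ra), atoms_a=tuple(aa.split(",")),
        chain_b=cb, res_b=int(rb), atoms_b=tuple(ab.split(",")),
    )


@dataclass
class HBondPolicy:
    """Distance-only H-bond classification: bonded / marginal / non-bonded.

    ``bonded`` at distance <= ``cutoff_A`` (default 3.5 A), ``marginal`` up
    to ``cutoff_A + margin_A`` (default 4.0 A); the accepted (bond-preserved)
    class is bonded plus marginal when ``accept_marginal`` is set.
    """

    cutoff_A: float = 3.5
    margin_A: float = 0.5
    accept_marginal: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_A <= 0 or self.margin_A < 0:
            raise ValueError("cutoff must be > 0 and margin >= 0")


@dataclass
class HBondSummary:
    """Per-pair ensemble summary under a policy."""

    pair: str
    n_models: int
    n_usable: int
    n_bonded: int
    n_marginal: int
    accepted_fraction: float
    nonbonded_distances_A: np.ndarray  # strict > cutoff complement
    nonbonded_mean_A: float
    nonbonded_sd_A: float
    policy: HBondPolicy = field(default_factory=HBondPolicy)


@dataclass
class MWUResult:
    """Mann-Whitney U comparison of two distance samples."""

    u: float
    p_value: float
    method: str  # "exact" or "asymptotic"
    n1: int
    n2: int


# ---------------------------------------------------------------------------

def load_ensemble(paths) -> Ensemble:
    """Load models from PDB files (a glob pattern, a directory, or a path list).

    Models keep input (sorted) order; files that cannot be parsed raise a
    ValueError naming the file.
    """
    from biotite.structure.io.pdb import PDBFile

    if isinstance(paths, (str, Path)):
        p = Path(paths)
        if p.is_dir():
            file_list = sorted(p.glob("*.pdb"))
        else:
            file_list = sorted(Path(f) for f in glob(str(paths)))
    else:
        file_list = [Path(f) for f in paths]
    if not file_list:
        raise ValueError(f"no PDB files matched {paths!r}")
    models = []
    for f in file_list:
        try:
            pdb = PDBFile.read(str(f))
            arr = pdb.get_structure(model=1)
        except Exception as err:
            raise ValueError(f"unparseable PDB file {f}: {err}") from err
        atoms: dict[AtomKey, np.ndarray] = {}
        for k in range(arr.array_length()):
            key = (str(arr.chain_id[k]), int(arr.res_id[k]),
                   str(arr.res_name[k]), str(arr.atom_name[k]))
            atoms[key] = np.asarray(arr.coord[k], dtype=float)
        models.append(Model(source=str(f), atoms=atoms))
    return Ensemble(models=models)


def pair_distance(model: Model, spec: ResiduePairSpec) -> float:
    """Reduced Euclidean distance over all cross pairs of the spec's atoms.

    The default reduction is the minimum (carboxyl oxygens are chemically
    equivalent, so the closer one defines the contact).
    """
    coords_a = [model.find(spec.chain_a, spec.res_a, a) for a in spec.atoms_a]
    coords_b = [model.find(spec.chain_b, spec.res_b, b) for b in spec.atoms_b]
    if any(c is None for c in coords_a + coords_b):
        missing = [a for a, c in zip(spec.atoms_a, coords_a) if c is None]
        missing += [b for b, c in zip(spec.atoms_b, coords_b) if c is None]
        raise KeyError(f"model {model.source}: missing atom(s) {missing}")
    d = [float(np.linalg.norm(ca - cb)) for ca in coords_a for cb in coords_b]
    return min(d) if spec.reduction == "min" else float(np.mean(d))


def classify_hbond(distance_A: float, policy: HBondPolicy | None = None) -> str:
    """'bonded' (<= cutoff), 'marginal' (<= cutoff+margin) or 'nonbonded'."""
    if distance_A < 0:
        raise ValueError("distance must be >= 0")
    policy = policy or HBondPolicy()
    if distance_A <= policy.cutoff_A:
        return "bonded"
    if distance_A <= policy.cutoff_A + policy.margin_A:
        return "marginal"
    return "nonbonded"


def hbond_summary(ensemble: Ensemble, spec: ResiduePairSpec,
                  policy: HBondPolicy | None = None) -> HBondSummary:
    """Bonded fraction and non-bonded distance statistics for one residue pair.

    Models missing a required atom are flagged (counted, excluded from the
    statistics). The accepted fraction includes marginal contacts under the
    default policy; non-bonded statistics are computed over the strict
    ``> cutoff`` complement, so the margin only affects the fraction.
    """
    policy = policy or HBondPolicy()
    distances = []
    flagged = 0
    for model in ensemble.models:
        try:
            distances.append(pair_distance(model, spec))
        except KeyError:
            flagged += 1
    if not distances:
        raise ValueError("no usable models: every model is missing required atoms")
    d = np.asarray(distances)
    n_bonded = int(np.sum(d <= policy.cutoff_A))
    n_marginal = int(np.sum((d > policy.cutoff_A) & (d <= policy.cutoff_A + policy.margin_A)))
    accepted = n_bonded + (n_marginal if policy.accept_marginal else 0)
    nonbonded = d[d > policy.cutoff_A]
    return HBondSummary(
        pair=spec.name,
        n_models=ensemble.n_models,
        n_usable=len(distances),
        n_bonded=n_bonded,
        n_marginal=n_marginal,
        accepted_fraction=accepted / len(distances),
        nonbonded_distances_A=nonbonded,
        nonbonded_mean_A=float(nonbonded.mean()) if nonbonded.size else float("nan"),
        nonbonded_sd_A=float(nonbonded.std(ddof=1)) if nonbonded.size > 1 else float("nan"),
        policy=policy,
    )


def mann_whitney_u(sample1, sample2, mode: str = "auto") -> MWUResult:
    """Two-sided Mann-Whitney U comparison of two samples.

    ``mode='auto'`` uses the exact null distribution when both samples have
    at most 10 observations and there are no ties, otherwise the normal
    approximation with tie and continuity corrections. ``'exact'`` and
    ``'asymptotic'`` force the choice.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (x.size <= 10 and y.size <= 10 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError("mode must be 'auto', 'exact' or 'asymptotic'")
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MWUResult(u=float(res.statistic), p_value=float(res.pvalue),
                     method=method, n1=int(x.size), n2=int(y.size))


def compare_ensembles(
    ensemble1: Ensemble,
    ensemble2: Ensemble,
    spec: ResiduePairSpec,
    policy: HBondPolicy | None = None,
) -> dict:
    """Side-by-side H-bond summaries plus a Mann-Whitney test on the
    non-bonded distance distributions."""
    s1 = hbond_summary(ensemble1, spec, policy)
    s2 = hbond_summary(ensemble2, spec, policy)
    mwu = mann_whitney_u(s1.nonbonded_distances_A, s2.nonbonded_distances_A)
    return {"first": s1, "second": s2, "mwu": mwu}


def summary_to_json(summary: HBondSummary) -> str:
    d = {
        "pair": summary.pair,
        "n_models": summary.n_models,
        "n_usable": summary.n_usable,
        "n_bonded": summary.n_bonded,
        "n_marginal": summary.n_marginal,
        "accepted_fraction": summary.accepted_fraction,
        "nonbonded_mean_A": summary.nonbonded_mean_A,
        "nonbonded_sd_A": summary.nonbonded_sd_A,
        "cutoff_A": summary.policy.cutoff_A,
        "margin_A": summary.policy.margin_A,
    }
    return json.dumps(d, indent=1)
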