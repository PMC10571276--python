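"""Physicochemical descriptors, Murcko scaffolds, and fingerprint similarity.

Ten descriptors are computed per molecule with RDKit's standard definitions:
topological polar surface area (``tpsa``, Å²), Crippen logP (``logp``),
rotatable bonds (``rb``), hydrogen-bond donors and acceptors (``hbd``,
``hba`` — the Lipinski N/O-based counts, matching the conventions of the
oral-absorption rules), molecular weight (``mw``, Da), ring and aromatic
ring counts (``nring``, ``naring``, SSSR convention), quantitative estimate
of drug-likeness (``qed``), and fraction of sp3 carbons (``fsp3``).

Scaffolds are non-generic Bemis–Murcko frameworks: the ring systems plus
the linkers that connect them, side chains removed, atom and bond types
retained. Fingerprints are RDKit path-based fingerprints at their defaults
(2048 bits, maximum path length 7 bonds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from statistics import mean, stdev
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors as _D
from rdkit.Chem import Lipinski as _L
from rdkit.Chem import QED
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.DataStructs import BulkTanimotoSimilarity, TanimotoSimilarity

FP_NBITS = 2048
FP_MAX_PATH = 7


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


@dataclass(frozen=True)
class DescriptorVector:
    tpsa: float
    logp: float
    rb: int
    hbd: int
    hba: int
    mw: float
    nring: int
    naring: int
    qed: float
    fsp3: float

    NAMES = ("tpsa", "logp", "rb", "hbd", "hba", "mw", "nring", "naring", "qed", "fsp3")

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite descriptor in {self}")
        if self.naring > self.nring:
            raise ValueError("naring exceeds nring")
        if not (0.0 <= self.qed <= 1.0 and 0.0 <= self.fsp3 <= 1.0):
            raise ValueError("qed/fsp3 outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


def compute_descriptors(smiles: str) -> DescriptorVector:
    """Compute the 10 descriptors for one (normalized) structure."""
    mol = _mol(smiles)
    try:
        return DescriptorVector(
            tpsa=_D.TPSA(mol),
            logp=_D.MolLogP(mol),
            rb=_L.NumRotatableBonds(mol),
            hbd=_L.NHOHCount(mol),
            hba=_L.NOCount(mol),
            mw=_D.MolWt(mol),
            nring=_D.RingCount(mol),
            naring=_L.NumAromaticRings(mol),
            qed=QED.qed(mol),
            fsp3=_L.FractionCSP3(mol),
        )
    except Exception as exc:  # exotic atoms can break individual descriptors
        raise ValueError(f"descriptor computation failed for {smiles!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Scaffolds
# ---------------------------------------------------------------------------


def murcko_scaffold(smiles: str) -> Optional[str]:
    """Canonical non-generic Bemis–Murcko scaffold, or None for ringless molecules."""
    mol = _mol(smiles)
    if _D.RingCount(mol) == 0:
        return None
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    smi = Chem.MolToSmiles(scaffold)
    return smi or None


@dataclass(frozen=True)
class ScaffoldSetStats:
    """Per-compound-set scaffold summary.

    Ring counts and aromatic/heteroring fractions are averaged over *unique*
    scaffolds; the percentage of molecules with a scaffold is over all
    molecules in the set.
    """

    n_mols: int
    n_unique_scaffolds: int
    scaff_per_mol: float
    pct_mols_with_scaffold: float
    rings_per_scaffold_mean: float
    rings_per_scaffold_sd: float
    frac_aromatic_rings_mean: float
    frac_aromatic_rings_sd: float
    frac_hetero_rings_mean: float
    frac_hetero_rings_sd: float


def _ring_profile(scaffold_smiles: str) -> tuple[int, float, float]:
    """(n rings, fraction aromatic, fraction heteroatomic) of a scaffold.

    A ring is aromatic when all its bonds are aromatic; a heteroring contains
    at least one non-carbon atom. Heteroaromatic rings count toward both
    fractions.
    """
    mol = Chem.MolFromSmiles(scaffold_smiles)
    ri = mol.GetRingInfo()
    n = ri.NumRings()
    n_arom = 0
    n_het = 0
    for bond_ring, atom_ring in zip(ri.BondRings(), ri.AtomRings()):
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in bond_ring):
            n_arom += 1
        if any(mol.GetAtomWithIdx(a).GetAtomicNum() != 6 for a in atom_ring):
            n_het += 1
    return n, n_arom / n, n_het / n


def scaffold_set_stats(smiles_list: Sequence[str]) -> ScaffoldSetStats:
    """Scaffold statistics for one compound set (list of SMILES)."""
    if not smiles_list:
        raise ValueError("scaffold_set_stats requires at least one molecule")
    n_mols = len(smiles_list)
    scaffolds: list[str] = []
    n_with = 0
    for smi in smiles_list:
        s = murcko_scaffold(smi)
        if s is not None:
            n_with += 1
            scaffolds.append(s)
    unique = sorted(set(scaffolds))

    def _ms(values: list[float]) -> tuple[float, float]:
        if not values:
            return math.nan, math.nan
        return mean(values), (stdev(values) if len(values) > 1 else 0.0)

    profiles = [_ring_profile(s) for s in unique]
    rings_m, rings_sd = _ms([p[0] for p in profiles])
    arom_m, arom_sd = _ms([p[1] for p in profiles])
    het_m, het_sd = _ms([p[2] for p in profiles])
    return ScaffoldSetStats(
        n_mols=n_mols,
        n_unique_scaffolds=len(unique),
        scaff_per_mol=len(unique) / n_mols,
        pct_mols_with_scaffold=100.0 * n_with / n_mols,
        rings_per_scaffold_mean=rings_m,
        rings_per_scaffold_sd=rings_sd,
        frac_aromatic_rings_mean=arom_m,
        frac_aromatic_rings_sd=arom_sd,
        frac_hetero_rings_mean=het_m,
        frac_hetero_rings_sd=het_sd,
    )


# ---------------------------------------------------------------------------
# Fingerprints and similarity
# ---------------------------------------------------------------------------


def path_fingerprint(smiles: str):
    """2048-bit RDKit path fingerprint (max path 7 bonds); deterministic."""
    return Chem.RDKFingerprint(_mol(smiles), maxPath=FP_MAX_PATH, fpSize=FP_NBITS)


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto |AND|/|OR| on bit vectors; two empty fingerprints give 0.0."""
    if fp_a.GetNumOnBits() == 0 and fp_b.GetNumOnBits() == 0:
        return 0.0
    return TanimotoSimilarity(fp_a, fp_b)


def max_tanimoto_profile(
    query_smiles: Sequence[str], reference_smiles: Sequence[str]
) -> np.ndarray:
    """For each query molecule, its maximum Tanimoto similarity to the reference set."""
    if not reference_smiles:
        raise ValueError("reference set is empty")
    if not query_smiles:
        raise ValueError("query set is empty")
    ref_fps = [path_fingerprint(s) for s in reference_smiles]
    out = np.empty(len(query_smiles))
    for i, smi in enumerate(query_smiles):
        fp = path_fingerprint(smi)
        if fp.GetNumOnBits() == 0:
            out[i] = max(tanimoto(fp, r) for r in ref_fps)
        else:
            out[i] = max(BulkTanimotoSimilarity(fp, ref_fps))
    return out
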