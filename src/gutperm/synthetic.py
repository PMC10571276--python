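"""Synthetic compound libraries emulating the gut-permanence study conditions.

Three strata are generated from closed template grammars (guaranteeing
chemical validity and controllable descriptor profiles):

* **FL** — long-chain acylglycerol-like Lingerers: triacylglycerols,
  1,2-diacylglycerols, and neutral diacyl phosphoglycerides with random
  long saturated acyl chains (default C14–C20, the palmitic/stearic band
  that dominates dietary glycerides). Large, lipophilic, flexible,
  ringless, highly saturated; annotated with the four fatty-lipid chemical
  classes and a neutral-dominated pKa mix with an acid minority.
* **noFL** — small polar Lingerers: short mono- and di-carboxylic acids,
  polyols, amino-acid-like fragments, and simple benzenoids; acid and
  zwitterion enriched pKa sampling with almost no purely basic molecules.
* **Traverser** — drug-like molecules from a ring-plus-substituent grammar
  over aromatic and heteroaromatic cores; mostly compliant with the
  rule-of-five, neutral/basic enriched.

pKa pairs are drawn from per-stratum truncated normal distributions: they
emulate database-reported annotations, they are not predicted from
structure. ``label_noise`` flips permanence labels only (never structures
or descriptors), and every flip is recorded in the truth table. The
``separation`` knob in [0, 1] controls structural overlap between the
noFL-Lingerer and Traverser strata by sampling a fraction of each from the
other's grammar; 1.0 (the default) keeps the strata structurally disjoint.

All generated SMILES are canonical neutral parents: normalization leaves
them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .records import CompoundRecord, QuantStatus, Source, write_compound_table
from .set_assembly import DRUGBANK, GUT, GUT_SERUM, LINGERER, TRAVERSER

FL_LABELS = ("Glycerolipids", "Glycerophospholipids", "Fatty acyls", "Sphingolipids")
NOFL_LABELS = (
    "Organic acids and derivatives",
    "Organic oxygen compounds",
    "Benzenoids",
    "Organic nitrogen compounds",
    "Organosulfur compounds",
    "Hydrocarbons",
)
TRAVERSER_LABELS = (
    "Organoheterocyclic compounds",
    "Benzenoids",
    "Organic acids and derivatives",
    "Organic oxygen compounds",
    "Steroids and steroid derivatives",
    "Prenol lipids",
    "Other",
)

# -- noFL grammar: small polar fragments ------------------------------------

_NOFL_TEMPLATES = (
    "OC(=O)C{chain}",            # short fatty/organic acid
    "OC(=O)C{chain}C(=O)O",      # dicarboxylic acid
    "CC(O)C(=O)O",               # lactic-like
    "OCC(O){chain_o}CO",         # open-chain polyol
    "NC(C{chain})C(=O)O",        # amino-acid-like
    "Oc1ccccc1",                 # phenol
    "Oc1ccccc1O",                # catechol
    "OC(=O)c1ccccc1",            # benzoic acid
    "OC(=O)c1ccc(O)cc1",         # hydroxybenzoic acid
    "OCC1OC(O)C(O)C(O)C1O",      # pyranose-like
    "CSCCC(N)C(=O)O",            # thioether amino acid
    "OS(=O)(=O)c1ccccc1",        # arenesulfonic acid
)

# -- Traverser grammar: cores x substituents ---------------------------------

_TRAVERSER_CORES = (
    "c1ccc({X})cc1",
    "c1ccc({X})nc1",
    "c1cnc({X})nc1",
    "c1ccc2[nH]c({X})cc2c1",
    "c1ccc2nc({X})ccc2c1",
    "c1ccc2[nH]c({X})nc2c1",
    "c1cc({X})cs1",
    "c1cc({X})co1",
    "c1ccc(-c2ccc({X})nc2)cc1",
    "C1CCN(C{X_frag})CC1",
    "O=C(Nc1ccc({X})cc1)c1ccccc1",
)

_TRAVERSER_SUBS = (
    "O", "N", "Cl", "F", "C", "OC", "C(C)C", "C(=O)O", "C(=O)N",
    "CN1CCOCC1", "NC(C)=O", "S(N)(=O)=O", "CCN(C)C",
)


def _canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"grammar produced invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(round(v, 2))
    return float(np.clip(mean, lo, hi))


def _fl_pka(rng: np.random.Generator) -> tuple[float | None, float | None]:
    # neutral-dominated, acid minority, no basic groups
    if rng.random() < 0.25:
        return _trunc_normal(rng, 4.8, 0.8, 1.0, 6.5), None
    return None, None


def _nofl_pka(rng: np.random.Generator) -> tuple[float | None, float | None]:
    # acid/zwitterion enriched; purely basic molecules nearly absent
    acid = _trunc_normal(rng, 4.0, 1.0, 1.0, 6.5) if rng.random() < 0.80 else None
    base = None
    if acid is not None and rng.random() < 0.30:
        base = _trunc_normal(rng, 9.5, 0.8, 8.0, 12.0)
    return acid, base


def _traverser_pka(rng: np.random.Generator) -> tuple[float | None, float | None]:
    # neutral > basic > acid > zwitterion
    u = rng.random()
    if u < 0.45:
        return None, None
    if u < 0.75:
        return None, _trunc_normal(rng, 9.0, 0.8, 8.0, 12.0)
    if u < 0.93:
        return _trunc_normal(rng, 4.5, 1.0, 1.0, 6.5), None
    return (
        _trunc_normal(rng, 4.0, 1.0, 1.0, 6.5),
        _trunc_normal(rng, 9.5, 0.8, 8.0, 12.0),
    )


def _chain(n_carbons: int) -> str:
    return "C" * n_carbons


def _fl_smiles(rng: np.random.Generator, chain_length_range: tuple[int, int]) -> str:
    """One acylglycerol-like structure with random long acyl chains.

    Templates are esters of glycerol or of a neutral (dimethyl)
    phosphoglycerol core; the fatty-acyl chemotype enters as the ester-bound
    chains, mirroring the glyceride-dominated composition of the real gut
    fatty-lipid stratum.
    """
    lo, hi = chain_length_range
    draw = lambda: int(rng.integers(lo, hi + 1))
    kind = rng.random()
    if kind < 0.60:  # triacylglycerol
        a, b, c = draw(), draw(), draw()
        smi = f"{_chain(a)}C(=O)OCC(OC(=O){_chain(b)})COC(=O){_chain(c)}"
    elif kind < 0.80:  # 1,2-diacylglycerol
        a, b = draw(), draw()
        smi = f"{_chain(a)}C(=O)OCC(CO)OC(=O){_chain(b)}"
    else:  # diacyl phosphoglyceride (neutral dimethyl phosphate ester)
        a, b = draw(), draw()
        smi = f"{_chain(a)}C(=O)OCC(OC(=O){_chain(b)})COP(=O)(OC)OC"
    return _canonical(smi)


def _nofl_smiles(rng: np.random.Generator) -> str:
    template = _NOFL_TEMPLATES[rng.integers(len(_NOFL_TEMPLATES))]
    smi = template.format(
        chain=_chain(int(rng.integers(0, 4))),
        chain_o="C(O)" * int(rng.integers(1, 4)),
    )
    return _canonical(smi)


def _traverser_smiles(rng: np.random.Generator) -> str:
    core = _TRAVERSER_CORES[rng.integers(len(_TRAVERSER_CORES))]
    sub = _TRAVERSER_SUBS[rng.integers(len(_TRAVERSER_SUBS))]
    smi = core.format(X=sub, X_frag=sub)
    return _canonical(smi)


# ---------------------------------------------------------------------------
# Stratum generators
# ---------------------------------------------------------------------------


def generate_fl_library(
    n: int, chain_length_range: tuple[int, int] = (14, 20), seed: int = 0
) -> list[CompoundRecord]:
    """``n`` fatty-lipid Lingerer records (gut-only metabolites)."""
    lo, hi = chain_length_range
    if n < 0 or lo < 4 or hi < lo:
        raise ValueError(f"invalid n or chain range: n={n}, range={chain_length_range}")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        pka_a, pka_b = _fl_pka(rng)
        rec = CompoundRecord(
            id=f"FL{i:06d}",
            smiles=_fl_smiles(rng, chain_length_range),
            source=Source.HMDB_GUT,
            in_gut=True,
            in_serum=False,
            pka_strongest_acidic=pka_a,
            pka_strongest_basic=pka_b,
            chem_class=FL_LABELS[rng.integers(len(FL_LABELS))],
            quant_status=QuantStatus.QUANTIFIED,
        )
        records.append(rec)
    return records


def generate_nofl_library(n: int, seed: int = 0) -> list[CompoundRecord]:
    """``n`` small polar Lingerer records (gut-only metabolites)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        pka_a, pka_b = _nofl_pka(rng)
        records.append(
            CompoundRecord(
                id=f"NF{i:06d}",
                smiles=_nofl_smiles(rng),
                source=Source.HMDB_GUT,
                in_gut=True,
                in_serum=False,
                pka_strongest_acidic=pka_a,
                pka_strongest_basic=pka_b,
                chem_class=NOFL_LABELS[rng.integers(len(NOFL_LABELS))],
                quant_status=QuantStatus.QUANTIFIED,
            )
        )
    return records


def generate_traverser_library(n: int, seed: int = 0) -> list[CompoundRecord]:
    """``n`` drug-like Traverser records.

    Half are emitted as drug-set records, half as gut+serum metabolites, so
    both Traverser routes through set assembly are exercised.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        pka_a, pka_b = _traverser_pka(rng)
        as_drug = i % 2 == 0
        records.append(
            CompoundRecord(
                id=f"TR{i:06d}",
                smiles=_traverser_smiles(rng),
                source=Source.DRUGBANK if as_drug else Source.HMDB_GUT,
                in_gut=not as_drug,
                in_serum=not as_drug,
                pka_strongest_acidic=pka_a,
                pka_strongest_basic=pka_b,
                chem_class=TRAVERSER_LABELS[rng.integers(len(TRAVERSER_LABELS))],
                quant_status=None if as_drug else QuantStatus.QUANTIFIED,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkSpec:
    """Composition and noise model of a synthetic benchmark."""

    n_fl: int = 400
    n_nofl: int = 400
    n_traverser: int = 400
    chain_length_range: tuple[int, int] = (14, 20)
    separation: float = 1.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_fl, self.n_nofl, self.n_traverser) < 0:
            raise ValueError("stratum sizes must be >= 0")
        if sum(n > 0 for n in (self.n_fl, self.n_nofl, self.n_traverser)) < 2:
            raise ValueError("at least two strata must be non-empty")
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must be in [0, 0.5]")
        if not 0.0 <= self.separation:
            raise ValueError("separation must be >= 0")


def generate_benchmark(spec: BenchmarkSpec) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Concatenated labeled strata plus a truth table.

    The truth table records, per molecule: the stratum, the true permanence
    label, the assigned (possibly noise-flipped) label, and the flip flag.
    Records carry the assigned label in ``permanence_label``; compartment
    sets and FL flags are set consistently with the generating stratum.
    """
    rng = np.random.default_rng(spec.seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4)
    fl = generate_fl_library(spec.n_fl, spec.chain_length_range, int(sub_seeds[0]))
    nofl = generate_nofl_library(spec.n_nofl, int(sub_seeds[1]))
    trav = generate_traverser_library(spec.n_traverser, int(sub_seeds[2]))

    # separation < 1: structural mixing between noFL and Traverser grammars
    mix_p = max(0.0, 0.5 * (1.0 - min(spec.separation, 1.0)))
    if mix_p > 0:
        mix_rng = np.random.default_rng(int(sub_seeds[3]))
        for r in nofl:
            if mix_rng.random() < mix_p:
                r.smiles = _traverser_smiles(mix_rng)
        for r in trav:
            if mix_rng.random() < mix_p:
                r.smiles = _nofl_smiles(mix_rng)

    records: list[CompoundRecord] = []
    rows = []
    strata = [("FL", fl, LINGERER), ("noFL", nofl, LINGERER), ("Traverser", trav, TRAVERSER)]
    flip_rng = np.random.default_rng(spec.seed + 1)
    for name, recs, true_label in strata:
        for r in recs:
            if r.source is Source.DRUGBANK:
                r.compartment_set = DRUGBANK
            elif r.in_gut and r.in_serum:
                r.compartment_set = GUT_SERUM
            else:
                r.compartment_set = GUT
            r.fl_flag = name == "FL"
            assigned = true_label
            flipped = flip_rng.random() < spec.label_noise
            if flipped:
                assigned = LINGERER if true_label == TRAVERSER else TRAVERSER
            r.permanence_label = assigned
            records.append(r)
            rows.append((r.id, name, true_label, assigned, flipped))
    truth = pd.DataFrame(
        rows, columns=["id", "stratum", "true_label", "assigned_label", "flipped"]
    )
    return records, truth


def write_benchmark(
    records: Sequence[CompoundRecord], truth: pd.DataFrame, out_dir: str | Path, spec: BenchmarkSpec
) -> None:
    """Write compounds.csv (reader schema), truth.csv, and a spec echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_compound_table(records, out / "compounds.csv")
    truth.to_csv(out / "truth.csv", index=False)
    with open(out / "benchmark_spec.txt", "w", encoding="utf-8") as fh:
        fh.write(repr(spec) + "\n")
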