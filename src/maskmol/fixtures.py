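"""Synthetic fixture sets and dataset loading.

The fixture generator exhaustively enumerates every chemically valid
connected molecule up to a small heavy-atom count over a restricted element
set -- a deterministic desk-scale stand-in for the large public training
sets.  Fixture chemistry is neutral and stereo-free, so the charge and
chirality properties exercise only their zero/"unspecified" categories.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
from rdkit import Chem

from .molgraph import (
    Dataset,
    MolecularGraph,
    SmilesParseError,
    Vocabulary,
    canonical_smiles,
    pair_list,
    smiles_to_graph,
)

__all__ = [
    "FixtureSpec",
    "enumerate_small_molecules",
    "load_dataset",
    "dataset_from_smiles",
    "split_smiles",
    "read_smiles_file",
    "write_smiles_file",
]

_MAX_ENUMERABLE_ATOMS = 6
_MAX_ESTIMATED_COMBINATIONS = 5e8


@dataclass(frozen=True)
class FixtureSpec:
    max_heavy_atoms: int = 4
    elements: tuple[str, ...] = ("C", "N", "O")
    bond_orders: tuple[int, ...] = (1, 2, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_heavy_atoms < 1:
            raise ValueError("max_heavy_atoms must be >= 1")
        if not self.elements:
            raise ValueError("element set is empty")


def _estimated_size(spec: FixtureSpec) -> float:
    total = 0.0
    for n in range(1, spec.max_heavy_atoms + 1):
        total += len(spec.elements) ** n * (len(spec.bond_orders) + 1) ** (n * (n - 1) // 2)
    return total


_ORDER_TO_BOND = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def _connected(bonds: tuple[int, ...], pairs: list[tuple[int, int]], n: int) -> bool:
    if n == 1:
        return True
    adj = [[] for _ in range(n)]
    for (i, j), b in zip(pairs, bonds):
        if b:
            adj[i].append(j)
            adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == n


@functools.lru_cache(maxsize=8)
def _enumerate_cached(
    max_heavy_atoms: int, elements: tuple[str, ...], bond_orders: tuple[int, ...]
) -> tuple[str, ...]:
    pt = Chem.GetPeriodicTable()
    valence = {el: pt.GetDefaultValence(el) for el in elements}
    max_val = max(valence.values())
    out: set[str] = set()
    for n in range(1, max_heavy_atoms + 1):
        pairs = pair_list(n)
        perms = list(permutations(range(n)))
        # label-independent pre-filter of bond assignments
        rows = []
        for bonds in product((0,) + tuple(bond_orders), repeat=len(pairs)):
            sums = [0] * n
            for (i, j), b in zip(pairs, bonds):
                sums[i] += b
                sums[j] += b
            if max(sums, default=0) <= max_val and _connected(bonds, pairs, n):
                rows.append((bonds, tuple(sums)))
        pair_pos = {}
        for p, (i, j) in enumerate(pairs):
            pair_pos[(i, j)] = pair_pos[(j, i)] = p
        seen_keys: set = set()
        for labels in product(elements, repeat=n):
            caps = tuple(valence[el] for el in labels)
            for bonds, sums in rows:
                if any(s > c for s, c in zip(sums, caps)):
                    continue
                key = min(
                    (
                        tuple(labels[p[i]] for i in range(n)),
                        tuple(bonds[pair_pos[(p[i], p[j])]] for i, j in pairs),
                    )
                    for p in perms
                )
                if key in seen_keys:
                    continue
                seen_keys.add(key)
                mol = Chem.RWMol()
                for el in labels:
                    mol.AddAtom(Chem.Atom(el))
                for (i, j), b in zip(pairs, bonds):
                    if b:
                        mol.AddBond(i, j, _ORDER_TO_BOND[b])
                try:
                    Chem.SanitizeMol(mol)
                except Exception:
                    continue
                out.add(Chem.MolToSmiles(mol))
    return tuple(sorted(out))


def enumerate_small_molecules(spec: FixtureSpec) -> list[str]:
    """Every valid connected molecule within the spec, canonical and sorted.

    Exhaustive over node-labelled multigraphs within valence limits, pushed
    through sanitization, deduplicated up to isomorphism.  Deterministic.
    Refuses bounds whose combinatorial size is not desk-enumerable.
    """
    est = _estimated_size(spec)
    if spec.max_heavy_atoms > _MAX_ENUMERABLE_ATOMS or est > _MAX_ESTIMATED_COMBINATIONS:
        raise ValueError(
            f"refusing enumeration: ~{est:.2e} raw combinations for "
            f"max_heavy_atoms={spec.max_heavy_atoms} exceeds the desk-scale bound"
        )
    return list(_enumerate_cached(spec.max_heavy_atoms, spec.elements, spec.bond_orders))


# ---------------------------------------------------------------------------
# dataset IO
# ---------------------------------------------------------------------------

def read_smiles_file(path: str) -> list[str]:
    """One SMILES per line, UTF-8, blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_smiles_file(path: str, smiles: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in smiles:
            fh.write(s + "\n")


def dataset_from_smiles(
    smiles_list: list[str],
    vocab: Vocabulary,
    split: str = "train",
    property_fn=None,
    on_error: str = "abort",
) -> tuple[Dataset, list[tuple[int, str]]]:
    """Parse a SMILES list into a Dataset; returns (dataset, rejections).

    ``on_error`` is "abort" (raise naming the offending line) or "skip"
    (collect (line_number, message) rejections).  ``property_fn`` maps an
    RDKit mol to the per-graph scalar y.
    """
    if on_error not in ("abort", "skip"):
        raise ValueError("on_error must be 'abort' or 'skip'")
    graphs: list[MolecularGraph] = []
    canon: set[str] = set()
    errors: list[tuple[int, str]] = []
    for lineno, smi in enumerate(smiles_list, start=1):
        try:
            y = None
            if property_fn is not None:
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    raise SmilesParseError(f"cannot parse/sanitize SMILES: {smi!r}")
                y = float(property_fn(mol))
            g = smiles_to_graph(smi, vocab, y=y)
            graphs.append(g)
            canon.add(canonical_smiles(smi))
        except Exception as exc:
            if on_error == "abort":
                raise type(exc)(f"line {lineno}: {exc}") from None
            errors.append((lineno, str(exc)))
    return Dataset(graphs=graphs, canonical_smiles_set=canon, split=split), errors


def load_dataset(
    path: str,
    vocab: Vocabulary,
    split: str = "train",
    property_fn=None,
    on_error: str = "abort",
) -> tuple[Dataset, list[tuple[int, str]]]:
    """Read a SMILES file and parse it into a Dataset (see dataset_from_smiles)."""
    return dataset_from_smiles(
        read_smiles_file(path), vocab, split=split, property_fn=property_fn, on_error=on_error
    )


def split_smiles(
    smiles_list: list[str], valid_fraction: float = 0.2, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic shuffled train/valid split."""
    if not 0.0 < valid_fraction < 1.0:
        raise ValueError("valid_fraction must lie in (0, 1)")
    order = np.random.default_rng(seed).permutation(len(smiles_list))
    n_valid = max(1, int(round(valid_fraction * len(smiles_list))))
    valid_idx = set(order[:n_valid].tolist())
    train = [smiles_list[i] for i in range(len(smiles_list)) if i not in valid_idx]
    valid = [smiles_list[i] for i in range(len(smiles_list)) if i in valid_idx]
    return train, valid
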