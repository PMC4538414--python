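"""Pedigree records, validation, and kinship coefficients.

A pedigree is a table of (family id, individual id, father id, mother id,
sex, zygosity) records.  Unknown parents are coded "0"; the zygosity column
is "." for non-twins and otherwise a tag whose value ("MZ..."/"DZ...")
identifies the twin pair within the family.  Kinship coefficients are
computed per family by the standard recursion over a parents-first ordering,
so the familial relationship matrix (twice the kinship) is exact for
arbitrary inbred pedigrees.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PedigreeError

UNKNOWN = "0"
NO_ZYGOSITY = "."

COLUMNS = ["fid", "iid", "father", "mother", "sex", "zygosity"]


def _family_topological_order(iids, fathers, mothers) -> list[int]:
    """Indices ordered parents-first within one family; raises on cycles."""
    idx = {iid: i for i, iid in enumerate(iids)}
    parents = [
        [idx[p] for p in (fathers[i], mothers[i]) if p in idx]
        for i in range(len(iids))
    ]
    state = np.zeros(len(iids), dtype=np.int8)  # 0 new, 1 open, 2 done
    order: list[int] = []
    for root in range(len(iids)):
        if state[root] != 0:
            continue
        stack = [(root, 0)]
        while stack:
            node, pi = stack.pop()
            if pi == 0:
                if state[node] == 2:
                    continue
                state[node] = 1
            if pi < len(parents[node]):
                stack.append((node, pi + 1))
                nxt = parents[node][pi]
                if state[nxt] == 1:
                    raise PedigreeError(f"individual {iids[nxt]!r} is its own ancestor")
                if state[nxt] == 0:
                    stack.append((nxt, 0))
            else:
                state[node] = 2
                order.append(node)
    return order


@dataclass
class Pedigree:
    """FAM-style records plus an MZ/DZ zygosity tag per individual."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if "zygosity" in missing:
            df["zygosity"] = NO_ZYGOSITY
            missing.remove("zygosity")
        if missing:
            raise PedigreeError(f"pedigree table lacks columns {missing}")
        for c in ("fid", "iid", "father", "mother", "zygosity"):
            df[c] = df[c].astype(str)
        if df["iid"].duplicated().any():
            dup = df.loc[df["iid"].duplicated(), "iid"].iloc[0]
            raise PedigreeError(f"duplicate individual id {dup!r}")
        self.table = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.table
        fid_of = pd.Series(df["fid"].values, index=df["iid"]).to_dict()
        for col in ("father", "mother"):
            pf = df[col].map(fid_of)
            bad = pf.notna() & (pf != df["fid"])
            if bad.any():
                row = df[bad].iloc[0]
                raise PedigreeError(
                    f"parent {row[col]!r} of {row['iid']!r} belongs to a different family"
                )
        for _, fam in self.families():
            _family_topological_order(
                fam["iid"].to_numpy(dtype=object),
                fam["father"].to_numpy(dtype=object),
                fam["mother"].to_numpy(dtype=object),
            )

    @property
    def ids(self) -> np.ndarray:
        return self.table["iid"].to_numpy(dtype=object)

    def families(self):
        return self.table.groupby("fid", sort=False)

    # -- relationship enumeration ------------------------------------------

    def spouse_pairs(self) -> list[tuple[str, str]]:
        """(father, mother) couples inferred from shared offspring."""
        df = self.table
        present = set(df["iid"])
        couples = df.loc[
            (df["father"] != UNKNOWN) & (df["mother"] != UNKNOWN), ["father", "mother"]
        ].drop_duplicates()
        return [
            (f, m)
            for f, m in couples.itertuples(index=False)
            if f in present and m in present
        ]

    def sibships(self) -> list[list[str]]:
        """Groups of individuals sharing both (known) parents."""
        df = self.table
        known = df[(df["father"] != UNKNOWN) & (df["mother"] != UNKNOWN)]
        return [
            g["iid"].tolist()
            for _, g in known.groupby(["fid", "father", "mother"], sort=False)
        ]

    def parent_offspring_pairs(self) -> list[tuple[str, str]]:
        df = self.table
        present = set(df["iid"])
        out = []
        for col in ("father", "mother"):
            sub = df[df[col].isin(present)]
            out.extend(zip(sub[col], sub["iid"]))
        return out

    def twin_groups(self) -> dict[tuple[str, str], list[str]]:
        """Map (fid, zygosity tag) -> member ids, for tagged individuals."""
        df = self.table
        tagged = df[df["zygosity"] != NO_ZYGOSITY]
        return {
            key: g["iid"].tolist()
            for key, g in tagged.groupby(["fid", "zygosity"], sort=False)
        }

    # -- kinship -----------------------------------------------------------

    def kinship_blocks(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-family (row indices, kinship block) pairs.

        Within each family the block entry (i, j) is the kinship coefficient
        phi_ij, with phi_ii = (1 + f_i)/2 for inbreeding coefficient f_i.
        Individuals in different families have kinship zero.
        """
        blocks = []
        for _, fam in self.families():
            rows = fam.index.to_numpy()
            iids = fam["iid"].to_numpy(dtype=object)
            fathers = fam["father"].to_numpy(dtype=object)
            mothers = fam["mother"].to_numpy(dtype=object)
            idx = {iid: i for i, iid in enumerate(iids)}
            order = _family_topological_order(iids, fathers, mothers)
            s = len(iids)
            phi = np.zeros((s, s))
            for pos, i in enumerate(order):
                fi = idx.get(fathers[i])
                mi = idx.get(mothers[i])
                phi[i, i] = 0.5 * (
                    1.0 + (phi[fi, mi] if fi is not None and mi is not None else 0.0)
                )
                earlier = order[:pos]
                if earlier:
                    v = np.zeros(len(earlier))
                    if fi is not None:
                        v += 0.5 * phi[fi, earlier]
                    if mi is not None:
                        v += 0.5 * phi[mi, earlier]
                    phi[i, earlier] = v
                    phi[earlier, i] = v
            blocks.append((rows, phi))
        return blocks

    def kinship_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense kinship matrix over all individuals (zero across families)."""
        n = len(self.table)
        phi = np.zeros((n, n))
        for rows, block in self.kinship_blocks():
            phi[np.ix_(rows, rows)] = block
        return self.ids, phi


def read_pedigree_tsv(path: str | os.PathLike) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(NO_ZYGOSITY)
    return Pedigree(df)


def write_pedigree_tsv(ped: Pedigree, path: str | os.PathLike) -> None:
    ped.table.to_csv(path, sep="\t", index=False)
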