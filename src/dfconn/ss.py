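"""Eight-class secondary-structure assignment (Kabsch–Sander scheme).

Backbone hydrogen bonds are detected with the classic electrostatic model

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

and a bond is accepted when E < -0.5 kcal/mol. Patterns map to the usual
classes: n->n+4 helix (H), n->n+3 (G), n->n+5 (I), bridges (E/B), turns (T),
bends (S, Cα pseudo-angle > 70°), otherwise '-'. Assignment priority is
H > E > B > G > I > T > S.

Amide hydrogens are taken from the topology when present, otherwise placed
1.0 Å from N along the direction of the preceding carbonyl C->O bond
reversed, as in the original algorithm. Prolines never donate. Bridges are
evaluated within a chain only.
"""

from __future__ import annotations

import warnings

import numpy as np

SS_CLASSES = ("H", "G", "I", "E", "B", "T", "S", "-")

_Q = 27.888          # kcal/mol·Å, dimensional constant of the H-bond energy
_E_CUT = -0.5        # kcal/mol
_BEND_ANGLE = 70.0   # degrees


def _chain_backbone(structure, coords):
    """Per chain: residue serials + N/CA/C/O/H coordinate arrays (NaN if absent)."""
    residues = structure.residues()
    serial = {key: i for i, key in enumerate(residues)}
    chains: dict[str, dict] = {}
    for chain in structure.chain_ids():
        keys = [k for k in residues if k[0] == chain]
        n = len(keys)
        data = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O", "H")}
        resnames = []
        for j, (ch, resid) in enumerate(keys):
            sel = np.nonzero((structure.chains == ch) & (structure.resids == resid))[0]
            resnames.append(structure.resnames[sel[0]] if len(sel) else "UNK")
            for a in sel:
                name = structure.atom_names[a]
                if name in ("N", "CA", "C", "O"):
                    data[name][j] = coords[a]
                elif name in ("H", "HN", "H1"):
                    data["H"][j] = coords[a]
        chains[chain] = {
            "serials": np.array([serial[k] for k in keys], dtype=int),
            "resnames": resnames,
            **data,
        }
    return chains


def _place_missing_h(cb) -> None:
    """DSSP hydrogen placement: H = N + unit(C_prev - O_prev)."""
    n = len(cb["serials"])
    for j in range(1, n):
        if not np.all(np.isnan(cb["H"][j])):
            continue
        c_prev, o_prev = cb["C"][j - 1], cb["O"][j - 1]
        nj = cb["N"][j]
        if np.any(np.isnan(c_prev)) or np.any(np.isnan(o_prev)) or np.any(np.isnan(nj)):
            continue
        v = c_prev - o_prev
        norm = np.linalg.norm(v)
        if norm > 0:
            cb["H"][j] = nj + v / norm


def _hbond_matrix(cb) -> np.ndarray:
    """hb[a, d] True if N-H of residue d donates to C=O of residue a (same chain)."""
    n = len(cb["serials"])
    hb = np.zeros((n, n), dtype=bool)
    C, O, N, H = cb["C"], cb["O"], cb["N"], cb["H"]
    donor_ok = np.array(
        [cb["resnames"][j] != "PRO" and not np.any(np.isnan(N[j] + H[j]))
         for j in range(n)]
    )
    acceptor_ok = np.array([not np.any(np.isnan(C[a] + O[a])) for a in range(n)])
    for a in range(n):
        if not acceptor_ok[a]:
            continue
        for d in range(n):
            if not donor_ok[d] or abs(a - d) < 2:
                continue
            r_on = np.linalg.norm(O[a] - N[d])
            r_ch = np.linalg.norm(C[a] - H[d])
            r_oh = np.linalg.norm(O[a] - H[d])
            r_cn = np.linalg.norm(C[a] - N[d])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, treat as no bond
            e = _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < _E_CUT:
                hb[a, d] = True
    return hb


def assign_frame_ss(structure, coords) -> np.ndarray:
    """Assign one of the 8 classes to every residue for a single frame.

    Returns an array of single-character labels in residue serial order.
    Residues missing backbone atoms are assigned '-' (with a warning).
    """
    coords = np.asarray(coords, dtype=float)
    n_res = len(structure.residues())
    out = np.full(n_res, "-", dtype="U1")
    chains = _chain_backbone(structure, coords)

    warned = False
    for cb in chains.values():
        n = len(cb["serials"])
        if n == 0:
            continue
        missing = np.any(np.isnan(cb["N"] + cb["CA"] + cb["C"] + cb["O"]), axis=1)
        if np.any(missing) and not warned:
            warnings.warn("residues with missing backbone atoms assigned '-'")
            warned = True
        _place_missing_h(cb)
        hb = _hbond_matrix(cb)

        # n-turns: C=O of i accepts from N-H of i+k
        turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
        for k in (3, 4, 5):
            for i in range(n - k):
                if hb[i, i + k]:
                    turn[k][i] = True

        labels = np.full(n, "-", dtype="U1")

        # bends (lowest priority, assigned first then overwritten)
        ca = cb["CA"]
        for i in range(2, n - 2):
            u = ca[i] - ca[i - 2]
            v = ca[i + 2] - ca[i]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu > 0 and nv > 0:
                cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
                if np.degrees(np.arccos(cosang)) > _BEND_ANGLE:
                    labels[i] = "S"

        # turns
        for k in (3, 4, 5):
            for i in np.nonzero(turn[k])[0]:
                for j in range(i + 1, min(i + k, n)):
                    labels[j] = "T"

        # bridges -> B/E
        bridge = np.zeros((n, n), dtype=bool)
        for i in range(1, n - 1):
            for j in range(i + 3, n - 1):
                para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
                anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
                if para or anti:
                    bridge[i, j] = bridge[j, i] = True
        has_bridge = bridge.any(axis=1)
        for i in np.nonzero(has_bridge)[0]:
            partners = np.nonzero(bridge[i])[0]
            extended = False
            for j in partners:
                for di in (-1, 1):
                    if 0 <= i + di < n and bridge[i + di, max(0, j - 1):j + 2].any():
                        extended = True
            labels[i] = "E" if extended else "B"

        # 3_10 (G) and pi (I): two consecutive turns of the same kind
        for k, cls in ((5, "I"), (3, "G")):
            for i in range(1, n - k):
                if turn[k][i - 1] and turn[k][i]:
                    for j in range(i, i + k):
                        if labels[j] not in ("E", "B"):
                            labels[j] = cls

        # alpha helix (H): highest priority
        for i in range(1, n - 4):
            if turn[4][i - 1] and turn[4][i]:
                labels[i:i + 4] = "H"

        labels[missing] = "-"
        out[cb["serials"]] = labels
    return out
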