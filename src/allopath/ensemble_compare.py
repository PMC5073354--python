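"""Ligand-induced structural-change detection between crystal structures.

The procedure: globally superpose the query onto the reference on all shared
backbone atoms, take per-residue Calpha deviations, call maximal runs of >= 3
consecutive residues all deviating by more than 0.5 Angstrom, then test each
run against the same residues' deviations in a third (unliganded-active-site)
structure with a two-tailed Welch t-test. A run deviating only in the query
is classified ligand-associated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import AllopathError, EmptyInputError
from .structio import (
    Ensemble,
    Selection,
    Structure,
    apply_transform,
    kabsch_superpose,
    match_atoms,
)

DEFAULT_THRESHOLD = 0.5  # Angstrom
DEFAULT_MIN_LEN = 3
DEFAULT_ALPHA = 0.05


@dataclass
class DeviationProfile:
    residues: list          # ordered residue keys shared by both structures
    ca_deviation: np.ndarray

    def as_dict(self) -> dict:
        return dict(zip(self.residues, self.ca_deviation))

    def __len__(self):
        return len(self.residues)


@dataclass
class Segment:
    start: tuple
    end: tuple
    residues: list
    mean_deviation: float
    max_deviation: float


@dataclass
class SegmentCall:
    segment: Segment
    p_value: float
    query_mean: float
    third_mean: float
    verdict: str  # ligand-associated | shared | indeterminate


def deviation_profile(query: Structure, reference: Structure) -> DeviationProfile:
    """Per-residue Calpha deviation after one global backbone superposition.

    Missing residues on either side (e.g. disordered loops) simply drop out
    of the shared set; they are never interpolated.
    """
    idx_q, idx_r = match_atoms(
        query, reference, Selection.backbone(), allow_unmatched=True
    )
    shared_res = {query.atoms[i].residue_key for i in idx_q}
    if len(shared_res) < 10:
        raise AllopathError(
            f"only {len(shared_res)} shared residues; global alignment unstable"
        )
    rot, trans, _ = kabsch_superpose(query.coords[idx_q], reference.coords[idx_r])
    moved = apply_transform(query.coords, rot, trans)

    idx_q_ca, idx_r_ca = match_atoms(
        query, reference, Selection.calpha(), allow_unmatched=True
    )
    residues, deviations = [], []
    for iq, ir in zip(idx_q_ca, idx_r_ca):
        residues.append(query.atoms[iq].residue_key)
        deviations.append(float(np.linalg.norm(moved[iq] - reference.coords[ir])))
    if not residues:
        raise EmptyInputError("no shared Calpha atoms between the structures")
    return DeviationProfile(residues=residues, ca_deviation=np.array(deviations))


def _consecutive(key_a: tuple, key_b: tuple) -> bool:
    """Adjacent in chain with no numbering gap; chain breaks terminate runs."""
    chain_a, seq_a, icode_a = key_a
    chain_b, seq_b, icode_b = key_b
    return chain_a == chain_b and seq_b == seq_a + 1 and icode_a == icode_b == ""


def find_segments(profile: DeviationProfile, threshold: float = DEFAULT_THRESHOLD,
                  min_len: int = DEFAULT_MIN_LEN) -> list[Segment]:
    """Maximal runs of consecutive residues all strictly above ``threshold``."""
    if len(profile) == 0:
        raise EmptyInputError("empty deviation profile")
    segments = []
    run: list[int] = []

    def flush():
        if len(run) >= min_len:
            devs = profile.ca_deviation[run]
            segments.append(
                Segment(
                    start=profile.residues[run[0]],
                    end=profile.residues[run[-1]],
                    residues=[profile.residues[i] for i in run],
                    mean_deviation=float(devs.mean()),
                    max_deviation=float(devs.max()),
                )
            )
        run.clear()

    for i, (key, dev) in enumerate(zip(profile.residues, profile.ca_deviation)):
        qualifies = dev > threshold
        if run and (not qualifies or not _consecutive(profile.residues[run[-1]], key)):
            flush()
        if qualifies:
            if run and not _consecutive(profile.residues[run[-1]], key):
                flush()
            run.append(i)
    flush()
    return segments


def classify_segments(segments, query_vs_ref: DeviationProfile,
                      third_vs_ref: DeviationProfile,
                      alpha: float = DEFAULT_ALPHA,
                      threshold: float = DEFAULT_THRESHOLD) -> list[SegmentCall]:
    """Welch-test each segment's query deviations against the third structure.

    Verdicts: ``shared`` when the third structure also exceeds the threshold
    over the segment (the change is not ligand-specific); otherwise
    ``ligand-associated`` when p < alpha and the query deviates more than the
    third; otherwise ``indeterminate``.
    """
    query_map = query_vs_ref.as_dict()
    third_map = third_vs_ref.as_dict()
    calls = []
    for seg in segments:
        shared_keys = [k for k in seg.residues if k in third_map and k in query_map]
        if len(shared_keys) < DEFAULT_MIN_LEN:
            raise AllopathError(
                f"segment {seg.start}-{seg.end} has only {len(shared_keys)} "
                "residues present in both profiles"
            )
        q = np.array([query_map[k] for k in shared_keys])
        t = np.array([third_map[k] for k in shared_keys])
        if np.allclose(q, t):
            p_value = 1.0
        else:
            result = stats.ttest_ind(q, t, equal_var=False)
            p_value = float(result.pvalue)
            if np.isnan(p_value):  # zero variance in both samples
                p_value = 0.0 if q.mean() != t.mean() else 1.0
        q_mean, t_mean = float(q.mean()), float(t.mean())
        if t_mean > threshold:
            verdict = "shared"
        elif p_value < alpha and q_mean > t_mean:
            verdict = "ligand-associated"
        else:
            verdict = "indeterminate"
        calls.append(
            SegmentCall(
                segment=seg,
                p_value=p_value,
                query_mean=q_mean,
                third_mean=t_mean,
                verdict=verdict,
            )
        )
    return calls


def compare_structures(query: Structure, reference: Structure, third: Structure,
                       threshold: float = DEFAULT_THRESHOLD,
                       min_len: int = DEFAULT_MIN_LEN,
                       alpha: float = DEFAULT_ALPHA) -> list[SegmentCall]:
    """End-to-end: profile, segment, classify (the Fig-2/4-style pipeline)."""
    q_profile = deviation_profile(query, reference)
    t_profile = deviation_profile(third, reference)
    segments = find_segments(q_profile, threshold, min_len)
    return classify_segments(segments, q_profile, t_profile, alpha, threshold)


def ensemble_rmsf(e: Ensemble, sel: Selection | None = None,
                  superpose: bool = True) -> dict:
    """Per-residue Calpha RMSF about the ensemble mean position.

    Frames are superposed onto frame 1 over the topology backbone unless
    ``superpose=False`` (caller already aligned them).
    """
    if len(e) < 2:
        raise AllopathError("RMSF requires at least 2 frames")
    sel = sel or Selection.calpha()
    topo = e.topology
    fit_idx = Selection.backbone().indices(topo)
    if fit_idx.size < 3:
        fit_idx = np.arange(len(topo))
    frames = [np.asarray(f, float) for f in e.frames]
    if superpose:
        ref = frames[0]
        aligned = [ref]
        for f in frames[1:]:
            rot, trans, _ = kabsch_superpose(f[fit_idx], ref[fit_idx])
            aligned.append(apply_transform(f, rot, trans))
        frames = aligned
    stack = np.stack(frames)               # (F, N, 3)
    idx = sel.require(topo)
    sub = stack[:, idx, :]
    mean = sub.mean(axis=0)
    msf = np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0)
    rmsf = np.sqrt(msf)
    out: dict = {}
    for val, i in zip(rmsf, idx):
        key = topo.atoms[i].residue_key
        out.setdefault(key, []).append(float(val))
    return {k: float(np.sqrt(np.mean(np.square(v)))) for k, v in out.items()}
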