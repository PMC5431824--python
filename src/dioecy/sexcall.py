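"""Molecular sexing from a panel of sex-linked SNP markers.

Candidate SNPs from the association scan are profiled on training samples of
known sex: each marker gets a per-sex majority genotype class (in an XY
system, females cluster at homozygous-reference "XX" and males at
heterozygous "XY") and a per-sex concordance. Markers with >= 90% concordance
in both sexes and distinct classes are 'strongly predictive' and form the
sexing panel. Unsexed samples are then called by majority vote over the
panel; samples whose markers give conflicting signals are flagged as putative
SDR recombinants, and samples with too few informative markers stay
undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StructuralError
from .types import GenotypeMatrix

CALL_FEMALE = "female"
CALL_MALE = "male"
CALL_RECOMBINANT = "putative_recombinant"
CALL_UNDETERMINED = "undetermined"


@dataclass
class MarkerProfile:
    """Per-SNP sex-concordance profile.

    ``female_class``/``male_class`` are the modal genotype classes (ALT
    dosage 0/1/2) among known females/males; ties break toward the lower
    dosage code. ``usable`` is False when a sex class has no non-missing
    training call at the SNP.
    """

    snp_id: str
    female_class: int | None
    male_class: int | None
    acc_female: float
    acc_male: float
    n_female: int
    n_male: int
    usable: bool = True

    @property
    def strongly_predictive(self) -> bool:
        """>= 90% concordance in both sexes (inclusive) and distinct classes."""
        return (self.usable
                and self.acc_female >= 0.90
                and self.acc_male >= 0.90
                and self.female_class != self.male_class)


def _majority_class(values: np.ndarray) -> tuple:
    """Modal dosage class and its frequency; ties -> lower dosage code."""
    vals = values[~np.isnan(values)].astype(int)
    if vals.size == 0:
        return None, np.nan, 0
    counts = np.bincount(vals, minlength=3)
    cls = int(np.argmax(counts))          # argmax takes the first (lowest) max
    return cls, counts[cls] / vals.size, int(vals.size)


def profile_markers(G: GenotypeMatrix, sexes: pd.Series,
                    candidates=None) -> list:
    """Profile candidate SNPs against known sex labels.

    Parameters
    ----------
    G : GenotypeMatrix
        Training genotypes.
    sexes : Series
        sample_id -> label; labels starting with 'F'/'M' (any case) count.
    candidates : sequence of SNP ids, optional
        Defaults to every SNP in ``G``.
    """
    sx = sexes.astype(str).str.upper().str[0]
    females = [s for s in G.samples if sx.get(s) == "F"]
    males = [s for s in G.samples if sx.get(s) == "M"]
    if not females or not males:
        raise StructuralError("need at least one known sample of each sex")
    if candidates is None:
        candidates = list(G.snps["id"])
    candidates = list(candidates)
    if not candidates:
        raise StructuralError("candidate SNP list is empty")

    col = {sid: j for j, sid in enumerate(G.snps["id"])}
    fi = G.sample_index(females)
    mi = G.sample_index(males)
    profiles = []
    for sid in candidates:
        j = col.get(sid)
        if j is None:
            raise StructuralError(f"candidate SNP {sid!r} not in matrix")
        f_cls, f_acc, f_n = _majority_class(G.dosages[fi, j])
        m_cls, m_acc, m_n = _majority_class(G.dosages[mi, j])
        usable = f_cls is not None and m_cls is not None
        profiles.append(MarkerProfile(
            snp_id=sid, female_class=f_cls, male_class=m_cls,
            acc_female=f_acc if usable else np.nan,
            acc_male=m_acc if usable else np.nan,
            n_female=f_n, n_male=m_n, usable=usable))
    return profiles


def profiles_to_frame(profiles) -> pd.DataFrame:
    return pd.DataFrame([{
        "snp_id": p.snp_id, "female_class": p.female_class,
        "male_class": p.male_class, "acc_female": p.acc_female,
        "acc_male": p.acc_male, "n_female": p.n_female, "n_male": p.n_male,
        "usable": p.usable, "strongly_predictive": p.strongly_predictive,
    } for p in profiles])


@dataclass
class EmptyPanelWarning:
    """Returned when no marker clears the predictiveness threshold."""

    n_candidates: int
    min_acc: float

    def __bool__(self) -> bool:
        return False


def select_predictive(profiles, min_acc: float = 0.90):
    """Keep markers with per-sex concordance >= min_acc (inclusive) and
    distinct sex classes, preserving input order. Returns an
    :class:`EmptyPanelWarning` when nothing qualifies."""
    panel = [p for p in profiles
             if p.usable
             and p.acc_female >= min_acc and p.acc_male >= min_acc
             and p.female_class != p.male_class]
    if not panel:
        return EmptyPanelWarning(n_candidates=len(list(profiles)),
                                 min_acc=min_acc)
    return panel


def cross_source_check(G_a: GenotypeMatrix, G_b: GenotypeMatrix,
                       shared_ids, panel, max_mismatch: float = 0.05,
                       max_mismatch_count: int | None = None) -> pd.DataFrame:
    """Genotype concordance of panel SNPs between two sequencing sources.

    Counts, per panel SNP, the shared samples whose non-missing genotype
    classes disagree between the sources. A SNP passes when its mismatch
    rate is <= ``max_mismatch`` (and, if ``max_mismatch_count`` is given,
    its mismatch count is <= that cap). SNPs with no overlapping
    non-missing calls are reported indeterminate (pass = NA).
    """
    shared_ids = list(shared_ids)
    if not shared_ids:
        raise StructuralError("no shared samples between sources")
    A = G_a.take_samples(shared_ids)
    B = G_b.take_samples(shared_ids)
    col_a = {sid: j for j, sid in enumerate(A.snps["id"])}
    col_b = {sid: j for j, sid in enumerate(B.snps["id"])}
    rows = []
    for p in panel:
        sid = p.snp_id if isinstance(p, MarkerProfile) else str(p)
        ja, jb = col_a.get(sid), col_b.get(sid)
        if ja is None or jb is None:
            raise StructuralError(f"panel SNP {sid!r} absent from a source")
        a, b = A.dosages[:, ja], B.dosages[:, jb]
        both = ~np.isnan(a) & ~np.isnan(b)
        n = int(both.sum())
        if n == 0:
            rows.append({"snp_id": sid, "n_shared_samples": 0,
                         "n_mismatches": 0, "mismatch_rate": np.nan,
                         "pass": pd.NA})
            continue
        mism = int(np.sum(a[both] != b[both]))
        rate = mism / n
        ok = rate <= max_mismatch
        if max_mismatch_count is not None:
            ok = ok and mism <= max_mismatch_count
        rows.append({"snp_id": sid, "n_shared_samples": n,
                     "n_mismatches": mism, "mismatch_rate": rate,
                     "pass": bool(ok)})
    return pd.DataFrame(rows)


@dataclass
class SexCallResult:
    sample_id: str
    call: str
    n_informative: int
    female_vote_fraction: float
    male_vote_fraction: float


def call_sex(G: GenotypeMatrix, panel, tau: float = 0.9,
             min_markers: int = 5) -> list:
    """Call sex for every sample in ``G`` by marker majority vote.

    Each panel SNP with a non-missing genotype votes female when it matches
    the marker's female class, male when it matches the male class, and
    abstains otherwise. A sample is called female (male) when the female
    (male) vote fraction among informative markers is >= ``tau``; with
    >= ``min_markers`` informative markers but no majority at ``tau`` the
    sample is a putative SDR recombinant; with fewer informative markers it
    is undetermined. Deterministic and order-independent over samples.
    """
    panel = [p for p in panel if isinstance(p, MarkerProfile)]
    if not panel:
        raise StructuralError("marker panel is empty")
    col = {sid: j for j, sid in enumerate(G.snps["id"])}
    cols, f_cls, m_cls = [], [], []
    for p in panel:
        j = col.get(p.snp_id)
        if j is None:
            raise StructuralError(f"panel SNP {p.snp_id!r} not in matrix")
        cols.append(j)
        f_cls.append(p.female_class)
        m_cls.append(p.male_class)
    d = G.dosages[:, cols]
    f_cls = np.array(f_cls, dtype=float)
    m_cls = np.array(m_cls, dtype=float)
    called = ~np.isnan(d)
    f_votes = (d == f_cls[None, :]) & called
    m_votes = (d == m_cls[None, :]) & called
    n_inf = (f_votes | m_votes).sum(axis=1)

    results = []
    for i, sid in enumerate(G.samples):
        ni = int(n_inf[i])
        if ni == 0:
            ff = mf = 0.0
        else:
            ff = float(f_votes[i].sum() / ni)
            mf = float(m_votes[i].sum() / ni)
        if ni < min_markers:
            call = CALL_UNDETERMINED
        elif ff >= tau:
            call = CALL_FEMALE
        elif mf >= tau:
            call = CALL_MALE
        else:
            call = CALL_RECOMBINANT
        results.append(SexCallResult(sample_id=sid, call=call,
                                     n_informative=ni,
                                     female_vote_fraction=ff,
                                     male_vote_fraction=mf))
    return results


def calls_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id, "call": r.call,
        "n_informative": r.n_informative,
        "female_vote_fraction": r.female_vote_fraction,
        "male_vote_fraction": r.male_vote_fraction,
    } for r in results])


def summarize_calls(results=None, *, n_female: int | None = None,
                    n_male: int | None = None, n_recombinant: int = 0,
                    n_undetermined: int = 0) -> dict:
    """Tally calls into class counts, the recombinant rate and the sex ratio.

    Accepts either a list of :class:`SexCallResult` or explicit class counts.
    recombinant_rate = n_recombinant / (n_female + n_male + n_recombinant);
    sex_ratio = n_male / n_female (None when no females).
    """
    if results is not None:
        n_female = sum(r.call == CALL_FEMALE for r in results)
        n_male = sum(r.call == CALL_MALE for r in results)
        n_recombinant = sum(r.call == CALL_RECOMBINANT for r in results)
        n_undetermined = sum(r.call == CALL_UNDETERMINED for r in results)
    if n_female is None or n_male is None:
        raise StructuralError("provide results or explicit counts")
    n_called = n_female + n_male + n_recombinant
    if n_called + n_undetermined == 0:
        return {}
    return {
        "n_female": int(n_female),
        "n_male": int(n_male),
        "n_recombinant": int(n_recombinant),
        "n_undetermined": int(n_undetermined),
        "n_called": int(n_called),
        "recombinant_rate": (n_recombinant / n_called) if n_called else 0.0,
        "sex_ratio": (n_male / n_female) if n_female else None,
    }
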