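"""Frozen cohort and concordance fixtures.

The 33-case cohort fixture reconstructs the published
clinicopathological series: every group-level marginal (group sizes,
MVP, calcifications, mitoses and Ki67 means/medians, INA/IDH/ATRX
counts, per-arm status counts, deletion-count means) equals its
published cell, and the textual joint constraints are honored (the
seven 9p-deleted OIII of which two are whole-chromosome-9 losses; the
single 1p-deleted AII carrying the 19q imbalance its column requires;
the one IDH1-R132H-negative OII rescued by IDH2 sequencing).  Joint
assignments beyond those constraints are arbitrary but frozen here in
construction order; case ids C01-C33 are synthetic.

The concordance fixtures freeze paired manual/automated status vectors
whose agreement counts equal the published 25/33 (chr9, 25/31 after
excluding the 2 weak-signal cases) and 23/33 (chr10, 22/28 after
excluding 5).  The disagreement pattern itself is not published and is
arbitrary-but-frozen; kappa on these fixtures is therefore internally
consistent but not a reproduction of the published coefficients.

Packaged CSV copies under ``data/`` are checksum-verified on load.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

_COHORT_COLUMNS = [
    "case_id", "group", "age", "sex", "recurrence", "mvp", "calcifications",
    "mitoses_per_10hpf", "ki67_pct", "ina_positive", "idh1r132h_positive",
    "idh2_mutant", "atrx", "necrosis", "status_1p", "status_19q",
    "status_9p", "status_10q", "control_9q_deleted", "control_10p_deleted",
]


def build_cohort_fixture() -> pd.DataFrame:
    """Construct the frozen 33-case cohort table."""
    rows = []

    def case(cid, group, age, sex, rec, mvp, calc, mit, ki67, ina, idh1,
             idh2, atrx, s1p, s19q, s9p, s10q, c9q=False):
        rows.append(dict(
            case_id=cid, group=group, age=age, sex=sex, recurrence=rec,
            mvp=mvp, calcifications=calc, mitoses_per_10hpf=mit,
            ki67_pct=ki67, ina_positive=ina, idh1r132h_positive=idh1,
            idh2_mutant=idh2, atrx=atrx, necrosis=False,
            status_1p=s1p, status_19q=s19q, status_9p=s9p, status_10q=s10q,
            control_9q_deleted=c9q, control_10p_deleted=False,
        ))

    # --- 13 OII: all codeleted, endocrinoid vessels, ATRX retained ---------
    oii_age = [30, 33, 36, 38, 40, 42, 42, 42, 45, 50, 55, 60, 72]
    oii_mit = [0, 0, 1, 1, 1, 2, 2, 2, 2, 2, 3, 3, 3]
    for k in range(13):
        cid = f"C{k + 1:02d}"
        case(cid, "OII", oii_age[k], "M" if k < 8 else "F",
             rec=(k == 0), mvp="endocrinoid",
             calc=cid in {"C01", "C03", "C05", "C07", "C09"},
             mit=oii_mit[k], ki67=10,
             ina=k < 11, idh1=k < 12, idh2=(k == 12),
             atrx="retained",
             s1p="DELETED", s19q="DELETED",
             s9p="IMBALANCED" if cid in {"C01", "C02"} else "NORMAL",
             s10q="IMBALANCED" if cid in {"C03", "C04"} else "NORMAL")

    # --- 10 OIII: codeleted, glomeruloid MVP; 7 9p-deleted, 2 of them
    #     whole-chromosome-9 losses (9q control arm also deleted) ----------
    oiii_age = [32, 36, 40, 42, 44, 44, 46, 50, 58, 78]
    oiii_mit = [4, 5, 5, 6, 6, 6, 7, 8, 10, 13]
    for k in range(10):
        cid = f"C{k + 14:02d}"
        case(cid, "OIII", oiii_age[k], "M" if k < 6 else "F",
             rec=cid in {"C14", "C15"}, mvp="glomeruloid",
             calc=cid in {"C14", "C16", "C18", "C20", "C22"},
             mit=oiii_mit[k], ki67=21,
             ina=k < 8, idh1=True, idh2=False, atrx="retained",
             s1p="DELETED", s19q="DELETED",
             s9p=("DELETED" if k < 7
                  else "NORMAL" if cid in {"C21", "C22"} else "IMBALANCED"),
             s10q="IMBALANCED" if cid == "C21" else "NORMAL",
             c9q=cid in {"C14", "C15"})

    # --- 3 AII: the single 1p-deleted case carries the 19q imbalance ------
    for k, (cid, s1p, s9p, s10q, atrx) in enumerate([
        ("C24", "DELETED", "NORMAL", "NORMAL", "lost"),
        ("C25", "IMBALANCED", "IMBALANCED", "NORMAL", "retained"),
        ("C26", "IMBALANCED", "NORMAL", "IMBALANCED", "retained"),
    ]):
        case(cid, "AII", [35, 38, 41][k], "F", rec=(cid == "C24"),
             mvp="endocrinoid", calc=False, mit=0, ki67=8,
             ina=False, idh1=True, idh2=False, atrx=atrx,
             s1p=s1p, s19q="IMBALANCED", s9p=s9p, s10q=s10q)

    # --- 3 AIII ------------------------------------------------------------
    for k, (cid, sex, calc, mit, s1p, s19q, s9p, atrx) in enumerate([
        ("C27", "M", True, 3, "DELETED", "NORMAL", "IMBALANCED", "lost"),
        ("C28", "M", True, 3, "NORMAL", "NORMAL", "NORMAL", "lost"),
        ("C29", "F", False, 5, "IMBALANCED", "IMBALANCED", "NORMAL", "retained"),
    ]):
        case(cid, "AIII", [33, 35, 49][k], sex, rec=True,
             mvp="endocrinoid", calc=calc, mit=mit, ki67=8,
             ina=False, idh1=True, idh2=False, atrx=atrx,
             s1p=s1p, s19q=s19q, s9p=s9p, s10q="NORMAL")

    # --- 4 GBM: all 9p-deleted, half 10q-deleted ---------------------------
    for k, (cid, sex, ki67, idh1, atrx, s1p, s19q, s10q) in enumerate([
        ("C30", "M", 15, True, "retained", "DELETED", "NORMAL", "DELETED"),
        ("C31", "M", 20, False, "lost", "IMBALANCED", "IMBALANCED", "DELETED"),
        ("C32", "F", 20, False, "retained", "NORMAL", "NORMAL", "NORMAL"),
        ("C33", "F", 37, False, "retained", "NORMAL", "NORMAL", "NORMAL"),
    ]):
        case(cid, "GBM", [38, 42, 44, 52][k], sex, rec=False,
             mvp="glomeruloid", calc=False, mit=[2, 5, 5, 5][k], ki67=ki67,
             ina=(cid == "C30"), idh1=idh1, idh2=False, atrx=atrx,
             s1p=s1p, s19q=s19q, s9p="DELETED", s10q=s10q)

    df = pd.DataFrame(rows, columns=_COHORT_COLUMNS)
    assert len(df) == 33
    return df


# Disagreeing cases for the paired manual/automated fixtures:
# {case_id: automated status}; manual is the cohort fixture's status.
_CHR9_DISAGREE = {
    "C01": "NORMAL", "C05": "IMBALANCED", "C12": "IMBALANCED",
    "C16": "IMBALANCED", "C22": "DELETED", "C24": "IMBALANCED",
    "C27": "NORMAL", "C31": "IMBALANCED",
}
_CHR9_WEAK = {"C12", "C22"}          # weak signal for both 9p and 9q

_CHR10_DISAGREE = {
    "C02": "IMBALANCED", "C03": "NORMAL", "C06": "IMBALANCED",
    "C08": "DELETED", "C13": "IMBALANCED", "C15": "IMBALANCED",
    "C17": "IMBALANCED", "C21": "NORMAL", "C26": "DELETED",
    "C29": "IMBALANCED",
}
_CHR10_WEAK = {"C02", "C08", "C15", "C29", "C33"}  # 3 weak + 2 with <50 cells


def build_concordance_fixture(chrom_id: str) -> pd.DataFrame:
    """Paired manual/automated calls for chr9 (9p) or chr10 (10q)."""
    cohort = build_cohort_fixture()
    col, disagree, weak = {
        "chr9": ("status_9p", _CHR9_DISAGREE, _CHR9_WEAK),
        "chr10": ("status_10q", _CHR10_DISAGREE, _CHR10_WEAK),
    }[chrom_id]
    rows = []
    for _, r in cohort.iterrows():
        manual = r[col]
        rows.append({
            "case_id": r["case_id"],
            "chromosome": chrom_id,
            "manual": manual,
            "automated": disagree.get(r["case_id"], manual),
            "interpretable": r["case_id"] not in weak,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged, checksum-verified copies
# ---------------------------------------------------------------------------

FIXTURE_BUILDERS = {
    "cohort": build_cohort_fixture,
    "concordance_chr9": lambda: build_concordance_fixture("chr9"),
    "concordance_chr10": lambda: build_concordance_fixture("chr10"),
}


def _data_dir() -> Path:
    return Path(str(resources.files("oligofish") / "data"))


def write_fixtures(out_dir: Path | None = None) -> dict[str, str]:
    """Write canonical fixture CSVs and their sha256 checksums."""
    out_dir = Path(out_dir) if out_dir else _data_dir()
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name, builder in FIXTURE_BUILDERS.items():
        path = out_dir / f"{name}.csv"
        builder().to_csv(path, index=False, lineterminator="\n")
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (out_dir / "checksums.json").write_text(
        json.dumps(checksums, indent=2) + "\n")
    return checksums


class FixtureIntegrityError(RuntimeError):
    """Raised when a packaged fixture fails checksum verification."""


def load_fixture(name: str, data_dir: Path | None = None) -> pd.DataFrame:
    """Load a packaged fixture CSV, verifying its sha256 checksum."""
    if name not in FIXTURE_BUILDERS:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {sorted(FIXTURE_BUILDERS)}")
    data_dir = Path(data_dir) if data_dir else _data_dir()
    path = data_dir / f"{name}.csv"
    recorded = json.loads((data_dir / "checksums.json").read_text())
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != recorded.get(name):
        raise FixtureIntegrityError(
            f"fixture {name!r} checksum mismatch: {digest} != {recorded.get(name)}")
    return pd.read_csv(path)


if __name__ == "__main__":
    for name, digest in write_fixtures().items():
        print(f"{name}: {digest}")
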