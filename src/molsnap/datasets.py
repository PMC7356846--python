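"""Molecule-level train/validation/test dataset construction.

Compounds are first shuffled (seeded) and dealt round-robin into n groups
(default 11), stratified by activity label so every group carries close to
the global active fraction. Two replicated dataset groups are then built at
the ratio Tra:Val:Test = 4:4:1 (groups, not compounds): replicate 01 takes
the first 4+4+1 groups; replicate 02 takes a previously unused group as its
fresh Test and re-draws 4+4 training/validation groups from the remainder.

Splitting happens strictly at the molecule level: every snapshot of one
compound lands in exactly one partition per replicate, which
:func:`check_no_leakage` verifies on any emitted manifest.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_prep import CompoundRecord, Conformer3D
from .snapshot import SnapshotConfig, snap_molecule

PARTITIONS = ("Tra", "Val", "Test")


@dataclass
class Replicate:
    replicate_id: str
    tra_groups: list[int]
    val_groups: list[int]
    test_group: int

    def partition_of(self, group: int) -> Optional[str]:
        if group in self.tra_groups:
            return "Tra"
        if group in self.val_groups:
            return "Val"
        if group == self.test_group:
            return "Test"
        return None


@dataclass
class SplitPlan:
    n_groups: int
    group_assignment: dict[str, int]  # compound_id -> group index
    replicates: list[Replicate] = field(default_factory=list)
    seed: int = 1

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {g: [] for g in range(self.n_groups)}
        for cid, g in self.group_assignment.items():
            out[g].append(cid)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_groups": self.n_groups,
            "seed": self.seed,
            "group_assignment": self.group_assignment,
            "replicates": [
                {"replicate_id": r.replicate_id, "tra_groups": r.tra_groups,
                 "val_groups": r.val_groups, "test_group": r.test_group}
                for r in self.replicates],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            n_groups=d["n_groups"], seed=d["seed"],
            group_assignment={k: int(v) for k, v in d["group_assignment"].items()},
            replicates=[Replicate(r["replicate_id"], list(r["tra_groups"]),
                                  list(r["val_groups"]), int(r["test_group"]))
                        for r in d["replicates"]])


def partition_groups(records: Sequence[CompoundRecord], n_groups: int = 11,
                     seed: int = 1) -> SplitPlan:
    """Seeded, label-stratified round-robin assignment into n groups.

    Group sizes differ by at most one overall and by at most one within each
    label stratum, so each group's active fraction tracks the global one.
    """
    kept = [r for r in records if r.kept]
    if len(kept) < n_groups:
        raise ValueError(f"need at least {n_groups} kept records, got {len(kept)}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0  # continue the round-robin across strata to balance totals
    for label in ("active", "inactive"):
        stratum = [r.compound_id for r in kept if r.label == label]
        order = rng.permutation(len(stratum))
        for k, idx in enumerate(order):
            assignment[stratum[idx]] = (offset + k) % n_groups
        offset += len(stratum)
    return SplitPlan(n_groups=n_groups, group_assignment=assignment, seed=seed)


def build_replicates(plan: SplitPlan, ratio: tuple[int, int, int] = (4, 4, 1),
                     n_replicates: int = 2) -> SplitPlan:
    """Fill the plan with replicated Tra/Val/Test group draws.

    Each replicate uses sum(ratio) of the n groups; every replicate's Test
    group is fresh (never used as Test before). Group order within a
    replicate is drawn deterministically from the plan seed.
    """
    n_tra, n_val, n_test = ratio
    need = n_tra + n_val + n_test
    if plan.n_groups < need + (n_replicates - 1) * n_test:
        raise ValueError(
            f"{plan.n_groups} groups cannot supply {n_replicates} replicates "
            f"with fresh test groups at ratio {ratio}")
    rng = np.random.default_rng(plan.seed + 1)
    used_test: set[int] = set()
    replicates = []
    for rep in range(n_replicates):
        candidates = [g for g in range(plan.n_groups) if g not in used_test]
        test_group = int(rng.choice(candidates))
        used_test.add(test_group)
        pool = [g for g in range(plan.n_groups) if g != test_group]
        drawn = list(rng.permutation(pool)[: n_tra + n_val])
        replicates.append(Replicate(
            replicate_id=f"{rep + 1:02d}",
            tra_groups=sorted(int(g) for g in drawn[:n_tra]),
            val_groups=sorted(int(g) for g in drawn[n_tra:]),
            test_group=test_group))
    plan.replicates = replicates
    return plan


# ---------------------------------------------------------------------------
# dataset emission


MANIFEST_COLUMNS = ["image_path", "compound_id", "theta_x", "theta_y",
                    "theta_z", "label", "partition", "replicate"]


def emit_dataset(records: Sequence[CompoundRecord],
                 conformers: dict[str, Conformer3D],
                 plan: SplitPlan,
                 out_dir: str | Path,
                 config: SnapshotConfig = SnapshotConfig()) -> pd.DataFrame:
    """Render snapshots into per-replicate class-labeled directory trees.

    Layout: ``<out>/replicate_<id>/<partition>/<label>/<image>.png`` with a
    ``manifest.csv`` at the root. Snapshots are rendered once per compound
    into a shared pool and copied into each replicate tree. Compounds with
    no conformer are logged in ``skipped.csv`` and omitted.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pool = out / "_pool"
    by_id = {r.compound_id: r for r in records if r.kept}

    rows = []
    skipped = []
    rendered: dict[str, list] = {}
    for cid, group in plan.group_assignment.items():
        rec = by_id.get(cid)
        if rec is None:
            continue
        if cid not in conformers:
            skipped.append(cid)
            continue
        images = snap_molecule(conformers[cid], config, out_dir=pool)
        rendered[cid] = images
        for replicate in plan.replicates:
            part = replicate.partition_of(group)
            if part is None:
                continue
            dest_dir = out / f"replicate_{replicate.replicate_id}" / part / rec.label
            dest_dir.mkdir(parents=True, exist_ok=True)
            for im in images:
                dest = dest_dir / im.filename
                shutil.copyfile(pool / im.filename, dest)
                rows.append({
                    "image_path": str(dest.relative_to(out)),
                    "compound_id": cid,
                    "theta_x": im.pose.angles[0],
                    "theta_y": im.pose.angles[1],
                    "theta_z": im.pose.angles[2],
                    "label": rec.label,
                    "partition": part,
                    "replicate": replicate.replicate_id,
                })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    if skipped:
        pd.DataFrame({"compound_id": skipped}).to_csv(out / "skipped.csv",
                                                      index=False)
    check_no_leakage(manifest)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"replicate": str, "compound_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return df


def check_no_leakage(manifest: pd.DataFrame) -> None:
    """Assert no compound's images straddle partitions within a replicate."""
    counts = (manifest.groupby(["replicate", "compound_id"])["partition"]
              .nunique())
    bad = counts[counts > 1]
    if len(bad):
        offenders = ", ".join(f"{cid}@rep{rep}" for rep, cid in bad.index[:5])
        raise AssertionError(
            f"molecule-level split violated: {offenders} appear in multiple "
            f"partitions")
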