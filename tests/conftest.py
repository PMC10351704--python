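from __future__ import annotations

import pandas as pd
import pytest

import wsdgat as w


@pytest.fixture(scope="session")
def study() -> w.simulate.StudyData:
    """Default two-group synthetic study with evolved sequences."""
    return w.simulate_study(seed=11)


@pytest.fixture(scope="session")
def calibrated_profile(study) -> w.ProfileModel:
    """Marker profile built from the ancestral domain plus a handful of
    leaf sequences, E-value calibrated on background decoys."""
    leaf = study.leaf_seqs
    aln = [w.DEFAULT_SEED_PROTEIN] + [leaf[k] for k in sorted(leaf)[:6]]
    prof = w.build_profile(aln)
    return w.calibrate_evalue(prof, decoy_lengths=150, n_decoys=1000, seed=99)


def sample_tables(sample: w.simulate.SampleData):
    """(hits-from-annotation, scaffold depths, fraction labels) frames for
    one simulated sample — the inputs of the abundance stage."""
    prot = sample.proteins
    hits = prot.loc[prot["domain"] != "", ["protein_id", "domain"]].rename(
        columns={"domain": "domain_id"}
    )
    scaffolds = pd.DataFrame(
        [
            {"scaffold_id": s.scaffold_id, "read_depth": s.read_depth}
            for s in sample.scaffolds
        ]
    )
    fractions = prot[["protein_id", "sample_id", "scaffold_id"]]
    return hits, scaffolds, fractions


@pytest.fixture(scope="session")
def family_sequences(study) -> dict[str, str]:
    """protein_id -> sequence for every emitted marker-family protein."""
    allp = study.all_proteins()
    fam = allp[allp["gene_class"] == "family"]
    return dict(zip(fam["protein_id"], fam["seq"]))
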