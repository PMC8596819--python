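import json

import pytest

from deskdock import (
    EmbedderSpec,
    Ligand,
    ReceptorProfile,
    embed_3d,
    enumerate_states,
    generate_toy_library,
    physchem_descriptors,
)


@pytest.fixture(scope="session")
def toy_library():
    return generate_toy_library(60, seed=11)


@pytest.fixture(scope="session")
def embedded_enums(toy_library):
    """20 single-state ligands from the toy library, embedded once per session."""
    enums = []
    for i, smi in enumerate(toy_library[:20]):
        lig = Ligand(ligand_id=f"T{i:02d}", input_smiles=smi)
        enumerate_states(lig, enumerate_stereo=False)
        for e in lig.enumerations[:1]:
            embed_3d(e, EmbedderSpec(max_iterations=200, seed=7))
            enums.append(e)
    return enums


@pytest.fixture(scope="session")
def receptor(toy_library):
    return ReceptorProfile("rec-test", target=physchem_descriptors(toy_library[0]))


@pytest.fixture
def run_config_factory(tmp_path, toy_library):
    """Write a ligand file + receptor JSON + run-config JSON into tmp_path."""

    def factory(n_ligands=5, tag="run", **overrides):
        smi_path = tmp_path / f"{tag}_ligands.smi"
        smi_path.write_text(
            "\n".join(f"{s} {tag}{i}" for i, s in enumerate(toy_library[:n_ligands])) + "\n"
        )
        rec_path = tmp_path / f"{tag}_receptor.json"
        rec_path.write_text(
            json.dumps(
                {
                    "identifier": "rec",
                    "target": list(physchem_descriptors(toy_library[0])),
                }
            )
        )
        conf = {
            "embedding": {
                "embedder": "rdkit",
                "parallelization": {"number_cores": 1, "max_compounds_per_core": 4},
                "parameters": {"max_iterations": 200, "seed": 7},
                "input": {"path": smi_path.name, "format": "SMILES"},
                "enumerate_stereo": False,
            },
            "docking": {
                "backend": "synthetic",
                "receptor": rec_path.name,
                "write_out_mode": "best_per_ligand",
            },
            "output": {
                "poses_path": f"{tag}_poses.sdf",
                "scores_path": f"{tag}_scores.csv",
            },
        }
        conf.update(overrides)
        conf_path = tmp_path / f"{tag}_conf.json"
        conf_path.write_text(json.dumps(conf))
        return conf_path

    return factory
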