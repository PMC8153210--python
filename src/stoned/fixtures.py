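"""Reference molecules used throughout the package and its tests.

SMILES literals are frozen from standard public structure records
(stereochemistry stripped, since the string grammar here encodes the flat
molecular graph).  Tests depend only on these literals, never on a lookup
service.  ``TOY`` holds small molecules for unit tests; the scaffold is a
reconstruction of a plausible 1,5-diarylpyrazole core for celecoxib
smoke-tests, not a published query.
"""

from __future__ import annotations

DRUGS: dict[str, str] = {
    "celecoxib": "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "aripiprazole": "O=C1CCc2cc(OCCCCN3CCN(c4cccc(Cl)c4Cl)CC3)ccc2N1",
    "albuterol": "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",
    "mestranol": "COc1ccc2c(c1)CCC1C2CCC2(C)C(O)(C#C)CCC12",
    "tadalafil": "CN1CC(=O)N2C(c3ccc4c(c3)OCO4)c3[nH]c4ccccc4c3CC2C1=O",
    "sildenafil": "CCCc1nn(C)c2c(=O)[nH]c(-c3cc(S(=O)(=O)N4CCN(C)CC4)ccc3OCC)nc12",
    "dihydroergotamine":
        "CN1CC(C(=O)NC2(C)OC3(O)C4CCCN4C(=O)C(Cc4ccccc4)N3C2=O)"
        "CC2c3cccc4[nH]cc(c34)CC21",
    "prinomastat": "ONC(=O)C1C(C)(C)SCCN1S(=O)(=O)c1ccc(Oc2ccncc2)cc1",
}

TOY: dict[str, str] = {
    "ethanol": "CCO",
    "ethane": "CC",
    "methanol": "CO",
    "benzene": "c1ccccc1",
    "cyclohexane": "C1CCCCC1",
    "norbornane": "C1CC2CCC1C2",
    "naphthalene": "c1ccc2ccccc2c1",
    "toluene": "Cc1ccccc1",
}

#: synthetic reconstruction of a celecoxib 1,5-diarylpyrazole core, used only
#: as a smoke-test scaffold query (SMARTS)
CELECOXIB_SCAFFOLD = "c1ccc(-n2nccc2-c2ccccc2)cc1"


def get(name: str) -> str:
    """Look up a fixture SMILES by molecule name."""
    for table in (DRUGS, TOY):
        if name in table:
            return table[name]
    raise KeyError(f"no fixture molecule named {name!r}")
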