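import textwrap

import pytest

from phylomint.fixtures import toy_networks_fig6


SBML_L3_TEMPLATE = textwrap.dedent("""\
    <?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
      <model id="{model_id}">
        <listOfCompartments>
          <compartment id="c" constant="true"/>
          <compartment id="e" constant="true"/>
        </listOfCompartments>
    {species_block}{reaction_block}  </model>
    </sbml>
""")


def make_sbml(model_id, species, reactions):
    """Build a minimal SBML Level-3 document.

    species: list of (id, boundary) tuples; reactions: list of
    (id, substrates, products, reversible) tuples.
    """
    sp_xml = "\n".join(
        f'      <species id="{sid}" compartment="c" constant="false"'
        f' boundaryCondition="{str(bnd).lower()}" hasOnlySubstanceUnits="false"/>'
        for sid, bnd in species
    )
    rx_chunks = []
    for rid, subs, prods, rev in reactions:
        reac = "\n".join(
            f'          <speciesReference species="{s}" constant="true" stoichiometry="1"/>'
            for s in subs
        )
        prod = "\n".join(
            f'          <speciesReference species="{p}" constant="true" stoichiometry="1"/>'
            for p in prods
        )
        parts = [f'      <reaction id="{rid}" reversible="{str(rev).lower()}" fast="false">']
        if subs:
            parts.append(f"        <listOfReactants>\n{reac}\n        </listOfReactants>")
        if prods:
            parts.append(f"        <listOfProducts>\n{prod}\n        </listOfProducts>")
        parts.append("      </reaction>")
        rx_chunks.append("\n".join(parts))
    species_block = (
        f"    <listOfSpecies>\n{sp_xml}\n    </listOfSpecies>\n" if species else ""
    )
    reaction_block = (
        "    <listOfReactions>\n" + "\n".join(rx_chunks) + "\n    </listOfReactions>\n"
        if reactions else ""
    )
    return SBML_L3_TEMPLATE.format(
        model_id=model_id, species_block=species_block, reaction_block=reaction_block
    )


@pytest.fixture
def toy_pair():
    return toy_networks_fig6()


@pytest.fixture
def five_reaction_sbml(tmp_path):
    """5 reactions, 1 of them an exchange -> 4 non-boundary after filtering."""
    text = make_sbml(
        "mini",
        species=[("M_a_c", False), ("M_b_c", False), ("M_c_c", False),
                 ("M_d_c", False), ("M_a_e", False)],
        reactions=[
            ("R1", ["M_a_c"], ["M_b_c"], False),
            ("R2", ["M_b_c"], ["M_c_c"], True),
            ("R3", ["M_b_c", "M_c_c"], ["M_d_c"], False),
            ("R4", ["M_a_e"], ["M_a_c"], False),
            ("EX_a_e", ["M_a_e"], [], False),
        ],
    )
    path = tmp_path / "mini.xml"
    path.write_text(text)
    return path
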