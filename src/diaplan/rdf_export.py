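"""Optional one-way export of the drug taxonomy and contraindication registry
to RDF (Turtle) for interoperability demonstrations.  Requires ``rdflib``
(install the ``rdf`` extra); nothing else in the package depends on it."""

from __future__ import annotations

from .knowledge_base import KnowledgeBase

BASE = "https://example.org/diaplan/"


def kb_to_turtle(kb: KnowledgeBase) -> str:
    from rdflib import RDF, RDFS, Graph, Literal, Namespace

    ns = Namespace(BASE)
    graph = Graph()
    graph.bind("dp", ns)

    for cls in kb.drug_classes.values():
        node = ns[f"class/{cls.name}"]
        graph.add((node, RDF.type, ns["DrugClass"]))
        graph.add((node, RDFS.label, Literal(cls.name)))
        graph.add((node, ns["mechanismOfAction"],
                   Literal(cls.mechanism_of_action)))
        if cls.parent:
            graph.add((node, RDFS.subClassOf, ns[f"class/{cls.parent}"]))
    for drug in kb.drugs.values():
        node = ns[f"drug/{drug.name}"]
        graph.add((node, RDF.type, ns[f"class/{drug.drug_class}"]))
        graph.add((node, RDFS.label, Literal(drug.name)))
        graph.add((node, ns["cost"], Literal(drug.cost)))
        if drug.max_dose_per_day:
            graph.add((node, ns["maximumDosePerDay"],
                       Literal(drug.max_dose_per_day)))
    for i, ci in enumerate(kb.contraindications):
        node = ns[f"contraindication/{i}"]
        graph.add((node, RDF.type, ns["Contraindication"]))
        graph.add((node, ns["subject"], Literal(ci.subject)))
        graph.add((node, ns["kind"], Literal(ci.kind)))
        graph.add((node, ns["object"], Literal(ci.object)))
    return graph.serialize(format="turtle")
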