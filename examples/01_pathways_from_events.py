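"""Build clinical pathways from a raw longitudinal event table.

Events are prefixed by type (l_/c_/s_/d_/p_), ordered chronologically
within admissions, and diagnosis codes are generalized to ICD-9 level 3,
so "250.13" (diabetes with ketoacidosis) becomes "250" (diabetes
mellitus).
"""

from clinalign import EventType, MedicalEvent, cohort_from_events

events = [
    MedicalEvent("alice", "adm1", 1, EventType.LAB, "50912"),
    MedicalEvent("alice", "adm1", 2, EventType.PRESCRIPTION, "insulin"),
    MedicalEvent("alice", "adm1", 3, EventType.DIAGNOSIS, "250.13"),
    MedicalEvent("alice", "adm2", 10, EventType.SYMPTOM, "780.6"),
    MedicalEvent("alice", "adm2", 11, EventType.DIAGNOSIS, "428.0"),
]

cohort = cohort_from_events(events)
pathway = cohort.pathways["alice"]
print("pathway:        ", pathway.events)
print("admission index:", pathway.admission_index)
print("final-admission labels:", sorted(cohort.label_map["alice"]))
# The label set is what PDPS tries to predict from the events that came
# before the final admission (here: everything in adm1).
print("prediction input:", pathway.events_before_final_admission())
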