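format-version: 1.2
ontology: toy-apoptosis

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process
def: "Any process specifically pertinent to the functioning of integrated living units." []

[Term]
id: GO:0006915
name: apoptosis
namespace: biological_process
alt_id: GO:0006917
synonym: "programmed cell death" EXACT []
def: "A form of programmed cell death induced by external or internal signals." []
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0006916
name: anti-apoptosis
namespace: biological_process
def: "A process which directly inhibits any of the steps required for cell death by apoptosis." []
is_a: GO:0006915 ! apoptosis

[Term]
id: GO:0042981
name: regulation of apoptosis
namespace: biological_process
def: "Any process that modulates the occurrence or rate of cell death by apoptosis." []
relationship: part_of GO:0008150 ! biological_process

[Term]
id: GO:0043065
name: positive regulation of apoptosis
namespace: biological_process
def: "Any process that activates or increases the frequency, rate or extent of cell death by apoptosis." []
is_a: GO:0042981 ! regulation of apoptosis

[Term]
id: GO:0043066
name: negative regulation of apoptosis
namespace: biological_process
def: "Any process that stops, prevents or reduces the frequency, rate or extent of cell death by apoptosis." []
is_a: GO:0042981 ! regulation of apoptosis
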