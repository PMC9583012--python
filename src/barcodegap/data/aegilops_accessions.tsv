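accession	species
W-2	Ae. biuncialis
W-3	Ae. biuncialis
W-4	Ae. biuncialis
W-6	Ae. biuncialis
W-7	Ae. biuncialis
W-43	Ae. juvenalis
W-45	Ae. juvenalis
W-46	Ae. juvenalis
W-9	Ae. columnaris
W-106	Ae. columnaris
W-108	Ae. columnaris
W-109	Ae. columnaris
W-111	Ae. columnaris
W-112	Ae. columnaris
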