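# Controlled vocabulary of known plant SSP families (38 families), with the
# class and mode-of-action each family belongs to and the number of tomato
# members reported in the published taxonomy (metadata only; not used by the
# rule engine).  Classes: PTM, CRP, NonCysNonPTM, FunctionalPrecursor.
# Modes: Signal, Antimicrobial, PeptidaseInhibitor, Unknown.

CEP:        {class: PTM, mode_of_action: Signal, description: C-terminally encoded peptide, n_tomato: 21}
CLE:        {class: PTM, mode_of_action: Signal, description: Clavata/Embryo Surrounding Region, n_tomato: 43}
GLV/RGF/CLEL: {class: PTM, mode_of_action: Signal, description: Golven/Root Growth Factor, n_tomato: 12}
IDA:        {class: PTM, mode_of_action: Signal, description: Inflorescence Deficient in Abscission, n_tomato: 8}
PIP:        {class: PTM, mode_of_action: Signal, description: PAMP-induced Secreted Peptide, n_tomato: 4}
PSK:        {class: PTM, mode_of_action: Signal, description: Phytosulfokine, n_tomato: 8}
PSY:        {class: PTM, mode_of_action: Signal, description: Plant Peptide Containing Sulfated Tyrosine, n_tomato: 11}

2SA:        {class: CRP, mode_of_action: Antimicrobial, description: 2S Albumin, n_tomato: 2}
ECL:        {class: CRP, mode_of_action: Signal, description: Egg Cell 1-Like, n_tomato: 10}
EPFL:       {class: CRP, mode_of_action: Signal, description: Epidermal Patterning Factor-Like, n_tomato: 12}
GASA:       {class: CRP, mode_of_action: Signal, description: Gibberellic Acid Stimulated in Arabidopsis, n_tomato: 20}
HEVEIN:     {class: CRP, mode_of_action: Antimicrobial, description: Hevein, n_tomato: 9}
Kunitz:     {class: CRP, mode_of_action: PeptidaseInhibitor, description: Kunitz-P trypsin inhibitor, n_tomato: 17}
LAT52-POE:  {class: CRP, mode_of_action: Signal, description: LAT52/Pollen Ole e 1 Allergen, n_tomato: 19}
MEG:        {class: CRP, mode_of_action: Signal, description: Maternally Expressed Gene, n_tomato: 2}
N26:        {class: CRP, mode_of_action: Signal, description: Nodulin26, n_tomato: 1}
nsLTP:      {class: CRP, mode_of_action: Signal, description: non-specific Lipid Transfer Protein, n_tomato: 122}
PCY:        {class: CRP, mode_of_action: Signal, description: Plantcyanin/Chemocyanin, n_tomato: 46}
PDF:        {class: CRP, mode_of_action: Antimicrobial, description: Plant Defensin, n_tomato: 51}
RALF:       {class: CRP, mode_of_action: Signal, description: Rapid Alkalinization Factor, n_tomato: 11}
RC:         {class: CRP, mode_of_action: Signal, description: Root Cap, n_tomato: 2}
STIG-GRI:   {class: CRP, mode_of_action: Signal, description: Stigma1/GRI, n_tomato: 10}
T2SPI:      {class: CRP, mode_of_action: PeptidaseInhibitor, description: Potato type II proteinase inhibitor, n_tomato: 13}
THL:        {class: CRP, mode_of_action: Antimicrobial, description: Thionin-like, n_tomato: 18}
TPD:        {class: CRP, mode_of_action: Signal, description: Tapetum Determinant 1, n_tomato: 6}
Kaz:        {class: CRP, mode_of_action: PeptidaseInhibitor, description: Kazal family inhibitors, n_tomato: 2}
PDL:        {class: CRP, mode_of_action: Antimicrobial, description: Plant Defensin-like, n_tomato: 2}
LCR:        {class: CRP, mode_of_action: Unknown, description: Low-molecular weight Cys-rich, n_tomato: 3}
TAX:        {class: CRP, mode_of_action: Signal, description: Taximin, n_tomato: 3}
SCR/SP11:   {class: CRP, mode_of_action: Signal, description: S-locus Cysteine Rich, n_tomato: 4}

CTLA:       {class: NonCysNonPTM, mode_of_action: PeptidaseInhibitor, description: Cytotoxic T-lymphocyte antigen-2 alpha, n_tomato: 5}
GRP:        {class: NonCysNonPTM, mode_of_action: Unknown, description: Glycine-rich Protein, n_tomato: 6}
PhyCys:     {class: NonCysNonPTM, mode_of_action: PeptidaseInhibitor, description: Phytocystatin, n_tomato: 9}
PNP:        {class: NonCysNonPTM, mode_of_action: Signal, description: Plant Natriuretic Peptide, n_tomato: 7}
PRP669:     {class: NonCysNonPTM, mode_of_action: Unknown, description: Pro-rich Protein Group 669, n_tomato: 4}
Subln:      {class: NonCysNonPTM, mode_of_action: PeptidaseInhibitor, description: Subtilisin inhibitor, n_tomato: 17}

CAPE:       {class: FunctionalPrecursor, mode_of_action: Signal, description: CAP-derived Peptide, n_tomato: 14}
MtSUBPEP:   {class: FunctionalPrecursor, mode_of_action: Signal, description: Subtilisin-embedded Plant Elicitor Peptide, n_tomato: 3}
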