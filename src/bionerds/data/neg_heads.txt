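format
formats
file
files
algorithm
algorithms
method
methods
language
languages
identifier
identifiers
operating system
operating systems
scheme
schemes
procedure
procedures
protocol
protocols
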