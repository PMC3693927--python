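record
records
recorded
alignment
alignments
develop
developed
developing
develops
ran
run
runs
running
use
used
uses
using
usage
interface
interfaces
platform
platforms
implement
implemented
implementation
execute
executed
install
installed
download
downloaded
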