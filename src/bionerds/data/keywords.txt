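database
databases
ontology
ontologies
web service
web services
service
services
tool
tools
program
programs
software
package
packages
server
servers
repository
repositories
webserver
application
applications
suite
pipeline
toolkit
browser
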