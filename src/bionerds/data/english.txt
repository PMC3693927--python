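the
a
an
and
or
but
of
in
on
at
by
for
with
from
into
over
under
between
through
during
against
about
across
after
before
since
until
analysis
network
cluster
string
graph
record
data
result
results
study
studies
gene
genes
protein
proteins
sequence
sequences
cell
cells
sample
samples
value
values
table
figure
section
paper
article
author
authors
work
time
year
years
number
numbers
group
groups
set
sets
list
lists
model
models
test
tests
score
scores
rate
rates
level
levels
case
cases
type
types
form
forms
part
parts
point
points
line
lines
word
words
term
terms
name
names
text
texts
search
match
matches
change
changes
use
user
users
run
runs
process
processes
system
systems
approach
approaches
structure
structures
function
functions
feature
features
region
regions
site
sites
domain
domains
family
families
species
organism
organisms
genome
genomes
expression
pathway
pathways
interaction
interactions
annotation
annotations
measure
measures
example
examples
problem
problems
question
questions
answer
answers
source
sources
target
targets
order
control
controls
effect
effects
error
errors
noise
signal
signals
input
inputs
output
outputs
step
steps
stage
stages
phase
phases
field
fields
area
areas
range
ranges
limit
limits
bound
bounds
mean
median
standard
deviation
distribution
distributions
frequency
frequencies
count
counts
total
totals
fraction
fractions
ratio
ratios
percent
percentage
index
indices
map
maps
key
keys
entry
entries
item
items
unit
units
size
sizes
length
lengths
width
height
depth
weight
mass
volume
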